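import numpy as np
import pytest

from dpescan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def two_group_cohort():
    """Small M-vs-N cohort with strong effects and known truth."""
    cfg = SimConfig(
        n_exons=800, n_m=15, n_n=15, n_h=0, n_u=0,
        fraction_dpe=0.1, logfc_magnitude=2.0, sex_exon_fraction=0.02, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def full_cohort():
    """Reduced four-group cohort (M/N/H/U) with known truth."""
    cfg = SimConfig(
        n_exons=600, n_m=12, n_n=20, n_h=20, n_u=6,
        fraction_dpe=0.1, logfc_magnitude=2.5, seed=7,
    )
    return simulate_cohort(cfg)


def write_sam(path, reads, chrom_lengths):
    """Write a SAM file; reads are dicts with qname/chrom/pos/cigar/flag/mapq/..."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom, ln in chrom_lengths.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{ln}")
    for r in sorted(reads, key=lambda r: (r["chrom"], r["pos"])):
        seq_len = sum(int(n) for n, op in _cigar_ops(r["cigar"]) if op in "MIS=X")
        lines.append(
            "\t".join([
                r["qname"], str(r.get("flag", 0)), r["chrom"], str(r["pos"] + 1),
                str(r.get("mapq", 60)), r["cigar"],
                r.get("rnext", "*"), str(r.get("pnext", 0)), str(r.get("tlen", 0)),
                "A" * seq_len, "I" * seq_len,
            ])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _cigar_ops(cigar):
    import re

    return [(m.group(1), m.group(2)) for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar)]
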