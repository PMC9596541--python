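"""Reference values from a published red clover pool-GBS extremes experiment.

A selective-genotyping study of stem-elongation timing in red clover
(*Trifolium pratense* cv. Lea) sequenced three replicate pools of each of
the 52 earliest and 52 latest elongating individuals and reported, for the
15 chromosomally placed loci significant under all three differentiation
tests, the marker positions and early/late group allele frequencies, plus
the genome-wide marker counts after filtering.  These printed values serve
as worked-example inputs: re-computing the two-group F_ST from each locus'
frequencies reproduces the published F_ST range, and the marker counts
reproduce the published chromosome-anchoring percentages and haplotype
density.
"""

from __future__ import annotations

import pandas as pd

# One row per reported significant marker (SNP or haplotype variant):
# locus label, library, marker kind, anchor position (bp), early / late
# group allele frequency (RAF for SNPs, variant frequency for haplotypes).
_SIGNIFICANT_LOCI = [
    ("1_0.76", "PstI", "snp", 1, 760722, 0.27, 0.95),
    ("1_1.16", "PstI", "htp", 1, 1162890, 0.37, 0.70),
    ("1_7.60", "PstI", "snp", 1, 7596707, 0.84, 1.00),
    ("1_10.40", "PstI", "snp", 1, 10404396, 0.33, 0.95),
    ("1_10.40", "PstI", "snp", 1, 10404400, 0.32, 0.95),
    ("1_10.40", "PstI", "snp", 1, 10404420, 0.33, 0.95),
    ("1_10.40", "PstI", "snp", 1, 10404428, 0.33, 0.95),
    ("1_12.58", "PstI", "snp", 1, 12578823, 1.00, 0.82),
    ("1_24.28", "ApeKI", "htp", 1, 24282619, 0.90, 0.09),
    ("1_24.28", "ApeKI", "htp", 1, 24282619, 0.51, 0.46),
    ("3_5.42", "ApeKI", "htp", 3, 5423909, 0.83, 0.17),
    ("3_5.42", "ApeKI", "htp", 3, 5423909, 0.30, 0.70),
    ("3_8.10", "ApeKI", "snp", 3, 8098050, 0.43, 0.80),
    ("3_30.48", "PstI", "snp", 3, 30484514, 0.14, 0.58),
    ("4_12.26", "PstI", "snp", 4, 12255468, 1.00, 0.48),
    ("4_17.77", "PstI", "snp", 4, 17771667, 0.96, 0.14),
    ("6_10.41", "ApeKI", "snp", 6, 10405305, 1.00, 0.56),
    ("6_19.51", "PstI", "snp", 6, 19510781, 0.85, 1.00),
    ("6_21.88", "ApeKI", "snp", 6, 21881050, 0.38, 0.88),
    ("6_21.88", "ApeKI", "htp", 6, 21881007, 0.38, 0.62),
    ("6_21.88", "ApeKI", "htp", 6, 21881007, 0.89, 0.11),
    ("7_14.52", "PstI", "snp", 7, 14523935, 1.00, 0.63),
    ("7_14.52", "PstI", "htp", 7, 14523913, 1.00, 0.63),
    ("7_14.52", "PstI", "snp", 7, 14523937, 1.00, 0.63),
    ("7_14.52", "PstI", "htp", 7, 14523913, 0.00, 0.37),
]


def load_significant_loci() -> pd.DataFrame:
    """The 15 chromosomal consensus loci with their reported markers.

    Columns: locus, library, kind (snp/htp), chrom, pos, q_early, q_late.
    """
    return pd.DataFrame(
        _SIGNIFICANT_LOCI,
        columns=["locus", "library", "kind", "chrom", "pos", "q_early", "q_late"],
    )


# Genome-wide marker counts after filtering, and the chromosome-anchored
# reference length, as reported by the same study.
MARKER_COUNTS = {
    "snps_psti": 12074,
    "snps_apeki": 91136,
    "snps_chromosomal": 66458,
    "htps_psti": 4653,
    "htps_apeki": 41073,
    "htps_chromosomal": 30215,
    "chromosome_anchored_mb": 164,
}
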