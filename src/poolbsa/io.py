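"""TSV / VCF / BED dialects used across the pipeline.

All tables are tab-separated with a header row.  SNP (RAF) tables are wide:
``chrom, pos, ref, alt`` followed by ``{pool}_ref_count, {pool}_alt_count,
{pool}_raf, {pool}_p_ref, {pool}_p_alt`` for each of the six pools.
Haplotype tables carry one row per (locus, variant) with per-pool counts
and relative frequencies.  Coordinates are 1-based inclusive except BED
exports, which are 0-based half-open.
"""

from __future__ import annotations

import pandas as pd

from .pools import PoolSpec


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_raf_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df


def read_htp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "haplotype": str})


def write_pools(pools: list[PoolSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "pool_id": p.pool_id,
                "group": p.group,
                "replicate": p.replicate,
                "n_individuals": p.n_individuals,
                "n_gametes": p.n_gametes,
            }
            for p in pools
        ]
    ).to_csv(path, sep="\t", index=False)


def read_pools(path) -> list[PoolSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        PoolSpec(group=r.group, replicate=int(r.replicate),
                 n_individuals=int(r.n_individuals))
        for r in df.itertuples()
    ]


def write_vcf(raf: pd.DataFrame, path) -> None:
    """Minimal VCF v4.2 export of SNP positions (CHROM, POS, REF, ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolbsa\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in raf.itertuples():
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED export (0-based half-open); expects chrom, start, end[, name]."""
    cols = [c for c in ("chrom", "start", "end", "name") if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)
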