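"""Marker quality filters for pooled allele-frequency tables.

SNP records carry per-pool reference/alternative read counts, a reference
allele frequency (RAF) and Bayesian allele-presence posteriors.  Six filter
stages are applied in a fixed order, the first four per pool ("per sample"),
the last two across the six pools of a library:

i.   drop records whose reference base is not A, C, G or T;
ii.  set a pool missing when both of its observed alleles differ from the
     reference, or its ref+alt read count is below ``min_allele_sum`` (30);
iii. zero the alternative allele (count and frequency) when
     p(freq_alt != 0) < ``posterior_cut`` (0.95); likewise the reference;
iv.  set a pool missing when the post-(iii) read count is below
     ``min_depth_after`` (27);
v.   drop records with more than two distinct remaining alleles across the
     six pools;
vi.  keep records with an informative RAF (within [0.05, 0.95], bounds
     inclusive) in at least one pool and non-missing data in all six.

Haplotype (HTP) loci are filtered by dropping variants that never exceed the
minor-frequency threshold in any pool, re-normalising, and requiring >= 2
surviving variants and >= ``min_locus_reads`` total reads in every pool.

Every stage logs entering/removed/surviving counts in a FilterReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pools import PoolSpec

VALID_BASES = {"A", "C", "G", "T"}


@dataclass
class FilterReport:
    """Per-stage record accounting; survivors are monotone non-increasing."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, entering: int, removed: int, note: str = "") -> None:
        surviving = entering - removed
        if surviving < 0:
            raise ValueError(f"stage {stage}: removed more records than entered")
        self.stages.append(
            {"stage": stage, "entering": entering, "removed": removed,
             "surviving": surviving, "note": note}
        )

    @property
    def n_in(self) -> int:
        return self.stages[0]["entering"] if self.stages else 0

    @property
    def n_out(self) -> int:
        return self.stages[-1]["surviving"] if self.stages else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def __str__(self) -> str:
        lines = [f"{'stage':<14}{'entering':>10}{'removed':>10}{'surviving':>11}  note"]
        for s in self.stages:
            lines.append(
                f"{s['stage']:<14}{s['entering']:>10}{s['removed']:>10}"
                f"{s['surviving']:>11}  {s['note']}"
            )
        return "\n".join(lines)


def _pool_ids(records: pd.DataFrame, pools) -> list[str]:
    if pools is not None:
        ids = [p.pool_id for p in pools]
    else:
        ids = sorted(
            {c.rsplit("_", 2)[0] for c in records.columns if c.endswith("_ref_count")}
        )
    if len(ids) != 6:
        raise ValueError(f"expected six pools per record, found {ids}")
    for pid in ids:
        for suffix in ("ref_count", "alt_count", "raf", "p_ref", "p_alt"):
            if f"{pid}_{suffix}" not in records.columns:
                raise ValueError(f"missing column {pid}_{suffix}")
    return ids


def filter_raf_table(
    records: pd.DataFrame,
    pools: list[PoolSpec] | None = None,
    min_allele_sum: int = 30,
    posterior_cut: float = 0.95,
    min_depth_after: int = 27,
    raf_lo: float = 0.05,
    raf_hi: float = 0.95,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply SNP filter stages i-vi in order; return survivors and a report.

    Optional columns ``{pool}_both_nonref`` (bool: both observed alleles
    differ from the reference; stage ii) and ``{pool}_alt_base`` (pool-wise
    alternative base; stage v allele accounting) are honoured when present;
    otherwise the record's global ``alt`` base is assumed everywhere and the
    both-non-reference condition never fires.
    """
    report = FilterReport()
    df = records.copy()
    ids = _pool_ids(df, pools)

    # stage i: valid reference base
    n0 = len(df)
    keep = df["ref"].astype(str).str.upper().isin(VALID_BASES)
    df = df[keep].copy()
    report.add("i_ref_base", n0, n0 - len(df), "reference base not A/C/G/T")

    missing = pd.DataFrame(False, index=df.index, columns=ids)

    # stage ii: per-pool missingness (non-reference allele pair or shallow)
    cells = 0
    for pid in ids:
        depth = df[f"{pid}_ref_count"].fillna(0) + df[f"{pid}_alt_count"].fillna(0)
        bad = depth < min_allele_sum
        flag_col = f"{pid}_both_nonref"
        if flag_col in df.columns:
            flag = df[flag_col].map(lambda v: bool(v) if pd.notna(v) else False)
            bad |= flag
        bad |= df[f"{pid}_raf"].isna()
        cells += int(bad.sum())
        missing[pid] |= bad
    report.add("ii_missing", len(df), 0, f"{cells} pool cells set missing")

    # stage iii: zero alleles failing the presence posterior
    zeroed = 0
    for pid in ids:
        alt_fail = df[f"{pid}_p_alt"] < posterior_cut
        ref_fail = df[f"{pid}_p_ref"] < posterior_cut
        zeroed += int(alt_fail.sum() + ref_fail.sum())
        df.loc[alt_fail, f"{pid}_alt_count"] = 0
        df.loc[ref_fail, f"{pid}_ref_count"] = 0
        depth = df[f"{pid}_ref_count"] + df[f"{pid}_alt_count"]
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"{pid}_raf"] = np.where(depth > 0, df[f"{pid}_ref_count"] / depth, np.nan)
    report.add("iii_posterior", len(df), 0, f"{zeroed} allele calls zeroed")

    # stage iv: residual depth
    cells = 0
    for pid in ids:
        depth = df[f"{pid}_ref_count"] + df[f"{pid}_alt_count"]
        bad = depth < min_depth_after
        cells += int((bad & ~missing[pid]).sum())
        missing[pid] |= bad
    report.add("iv_low_depth", len(df), 0, f"{cells} pool cells set missing")

    # stage v: at most two distinct alleles across the six pools
    n_pre = len(df)
    alleles_over = pd.Series(False, index=df.index)
    ref_upper = df["ref"].astype(str).str.upper()
    observed = [set() for _ in range(len(df))]
    for i, (_, row) in enumerate(df.iterrows()):
        pid_alleles = {ref_upper.iloc[i]}
        for pid in ids:
            if missing[pid].iloc[i]:
                continue
            if row[f"{pid}_alt_count"] > 0:
                alt_col = f"{pid}_alt_base"
                alt = row[alt_col] if alt_col in df.columns and pd.notna(row.get(alt_col)) else row["alt"]
                pid_alleles.add(str(alt).upper())
        observed[i] = pid_alleles
    alleles_over[:] = [len(a) > 2 for a in observed]
    df = df[~alleles_over.to_numpy()].copy()
    missing = missing.loc[df.index]
    report.add("v_biallelic", n_pre, n_pre - len(df), ">2 alleles across pools")

    # stage vi: informative RAF somewhere, complete data everywhere
    n_pre = len(df)
    raf = pd.DataFrame({pid: df[f"{pid}_raf"] for pid in ids})
    raf_masked = raf.mask(missing)
    informative = ((raf_masked >= raf_lo) & (raf_masked <= raf_hi)).any(axis=1)
    complete = ~missing.any(axis=1) & raf.notna().all(axis=1)
    df = df[informative & complete].copy()
    report.add("vi_informative", n_pre, n_pre - len(df),
               f"RAF in [{raf_lo}, {raf_hi}] in >=1 pool and data in all six")
    return df, report


def filter_htp_table(
    records: pd.DataFrame,
    pools: list[PoolSpec] | None = None,
    min_locus_reads: int = 30,
    min_variant_freq: float = 0.05,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter a haplotype table (one row per locus x variant).

    Variants that never exceed ``min_variant_freq`` in any pool are dropped
    and frequencies re-normalised; loci then need >= 2 surviving variants
    and >= ``min_locus_reads`` total reads in every pool.
    """
    report = FilterReport()
    df = records.copy()
    if pools is not None:
        ids = [p.pool_id for p in pools]
    else:
        ids = sorted({c.rsplit("_", 1)[0] for c in df.columns if c.endswith("_count")})
    if len(ids) != 6:
        raise ValueError(f"expected six pools per record, found {ids}")

    freq_cols = [f"{pid}_freq" for pid in ids]
    count_cols = [f"{pid}_count" for pid in ids]

    n0 = len(df)
    keep_variant = (df[freq_cols] > min_variant_freq).any(axis=1)
    df = df[keep_variant].copy()
    report.add("variant_maf", n0, n0 - len(df),
               f"variant frequency <= {min_variant_freq} in every pool")

    # re-normalise within locus per pool
    for pid in ids:
        totals = df.groupby("locus_id")[f"{pid}_count"].transform("sum")
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"{pid}_freq"] = np.where(totals > 0, df[f"{pid}_count"] / totals, 0.0)

    n1 = len(df)
    nvar = df.groupby("locus_id")["haplotype"].transform("count")
    df = df[nvar >= 2].copy()
    report.add("polymorphic", n1, n1 - len(df), "locus left with < 2 variants")

    n2 = len(df)
    locus_ok = df.groupby("locus_id")[count_cols].transform("sum").ge(min_locus_reads).all(axis=1)
    df = df[locus_ok].copy()
    report.add("locus_depth", n2, n2 - len(df),
               f"< {min_locus_reads} reads in some pool")
    return df, report


def maf_matrix(
    raf: pd.DataFrame,
    pools: list[PoolSpec] | None = None,
    chromosomal_only: bool = False,
) -> pd.DataFrame:
    """Markers x pools matrix of minor-allele frequencies.

    The minor allele is defined marker-wise from the mean RAF across pools:
    when the reference allele is the rarer one on average, MAF equals the
    RAF in every pool; otherwise 1 - RAF.  With ``chromosomal_only``, rows
    whose chromosome label is not a plain number (unplaced scaffolds) are
    excluded.
    """
    ids = _pool_ids(raf, pools)
    df = raf
    if chromosomal_only:
        placed = df["chrom"].astype(str).str.fullmatch(r"\d+")
        df = df[placed.fillna(False)]
    if df.empty:
        import warnings

        warnings.warn("empty RAF table; returning empty MAF matrix")
        return pd.DataFrame(columns=ids)
    mat = pd.DataFrame({pid: df[f"{pid}_raf"] for pid in ids})
    ref_minor = mat.mean(axis=1) <= 0.5
    out = mat.where(ref_minor, 1.0 - mat, axis=0)
    if {"chrom", "pos"}.issubset(df.columns):
        out.index = pd.Index(
            [f"{c}:{p}" for c, p in zip(df["chrom"], df["pos"])], name="marker"
        )
    return out
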