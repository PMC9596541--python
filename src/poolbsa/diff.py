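"""Allele-frequency differentiation tests for replicate extreme pools.

Two in-package tests contrast the early and late phenotype groups at every
marker, each with its own empirical false-discovery-rate calibration, plus
import/export of BayeScan's two-population text formats so an external
F_ST-outlier run can join the consensus:

* **Replicate F_ST test** ("method 1"): each of the six pools is compared
  against the gamete-weighted mean frequency of the three pools of the
  contrasting phenotype.  Pairwise F_ST = (mean(q^2) - mean(q)^2) /
  (mean(q) (1 - mean(q))) with gamete weights, tested via
  X^2 = 2N * F_ST ~ chi^2(1) where 2N is the summed gametes of the two
  compared units.  A marker is significant at level P only if all six
  comparisons are significant and the frequency deviations are directionally
  consistent (all early pools above the late mean and vice versa, or the
  reverse).  Because of this six-fold + two-direction requirement the FDR at
  level P is estimated as (l P^3 / d)^2 rather than the usual l P / d.

* **Error-variance test** ("method 2"): Z^2 = (qbar_L - qbar_E)^2 /
  (V1_L + V1_E + V2_L + V2_E) ~ chi^2(1), where qbar is the gamete-weighted
  mean over the three replicate pools of a group, V1 = qbar(1-qbar)/(2 N_ind)
  is the variance from sampling N_ind individuals per group, and
  V2 = sigma^2_rep / N_rep is the observed between-replicate variance.
  FDR at level P is the standard l P / d.

The `PoolContrast` / `ContrastResults` pair wraps these operations in a
model/results interface; the functions underneath are public and vectorised
over markers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pools import EARLY, LATE, PoolSpec

DEFAULT_P_GRID = np.logspace(-8, -1, 50)


# ---------------------------------------------------------------------------
# F_ST primitives
# ---------------------------------------------------------------------------

def _fst_arrays(q1, q2, w1, w2):
    """Vectorised weighted pairwise F_ST between two units.

    Returns 0 where the weighted mean frequency is 0 or 1 (no variance to
    apportion; extends the both-zero convention symmetrically).
    """
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        raise ValueError("weights must be positive")
    wsum = w1 + w2
    qbar = (w1 * q1 + w2 * q2) / wsum
    # mean(q^2) - mean(q)^2 reduces exactly to w1 w2 (q1-q2)^2 / (w1+w2)^2
    # for two units; the closed form avoids catastrophic cancellation
    num = w1 * w2 * (q1 - q2) ** 2 / wsum**2
    denom = qbar * (1.0 - qbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(fst, 0.0, 1.0)


def pairwise_fst(freqs: Sequence[float], gametes: Sequence[float]) -> float:
    """Weighted pairwise F_ST between two units.

    Parameters
    ----------
    freqs : sequence of two frequencies in [0, 1]
        Allele frequency in each compared unit.  A unit may itself be a
        weighted aggregate (e.g. the mean of three pools).
    gametes : sequence of two positive weights
        Number of gametes represented by each unit.

    Returns
    -------
    float
        F_ST = (mean(q^2) - mean(q)^2) / (mean(q)(1 - mean(q))), with the
        convention F_ST = 0 when the allele is absent (or fixed) in both
        units.
    """
    if len(freqs) != 2 or len(gametes) != 2:
        raise ValueError("pairwise_fst compares exactly two units")
    return float(_fst_arrays(freqs[0], freqs[1], gametes[0], gametes[1]))


def two_group_fst(q_early: float, q_late: float, weights: Sequence[float] = (1.0, 1.0)) -> float:
    """F_ST between the two phenotype-group aggregate frequencies.

    This is the per-marker summary used for reporting (e.g. Manhattan-style
    plots); by default the two groups are weighted equally.
    """
    return pairwise_fst([q_early, q_late], list(weights))


# ---------------------------------------------------------------------------
# Method 1: replicate F_ST test
# ---------------------------------------------------------------------------

def _split_pools(pools: Sequence[PoolSpec]) -> tuple[np.ndarray, np.ndarray]:
    early = np.array([i for i, p in enumerate(pools) if p.group == EARLY])
    late = np.array([i for i, p in enumerate(pools) if p.group == LATE])
    if len(early) != 3 or len(late) != 3:
        raise ValueError("design requires exactly 3 early and 3 late pools")
    return early, late


def method1_stats(freqs: np.ndarray, pools: Sequence[PoolSpec]) -> dict[str, np.ndarray]:
    """Vectorised six-comparison replicate F_ST test.

    Parameters
    ----------
    freqs : (n_markers, 6) array
        Reference-allele (or variant) frequency of each marker in each pool,
        columns ordered as ``pools``.  Rows containing NaN are skipped
        (all outputs NaN).
    pools : six PoolSpec

    Returns
    -------
    dict with per-marker arrays: ``fst`` and ``p`` of shape (n, 6) in pool
    order, ``max_p`` (worst of the six), ``direction_ok`` (bool), and
    ``direction`` (+1 early-high / -1 early-low / 0).
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if freqs.shape[1] != len(pools):
        raise ValueError("frequency matrix must have one column per pool")
    e_idx, l_idx = _split_pools(pools)
    gam = np.array([p.n_gametes for p in pools], dtype=float)

    n = freqs.shape[0]
    fst = np.full((n, 6), np.nan)
    pvals = np.full((n, 6), np.nan)
    diffs = np.full((n, 6), np.nan)

    for j in range(6):
        contrast = l_idx if j in set(e_idx) else e_idx
        wc = gam[contrast]
        q_contrast = freqs[:, contrast] @ wc / wc.sum()
        f = _fst_arrays(freqs[:, j], q_contrast, gam[j], wc.sum())
        two_n = gam[j] + wc.sum()
        chi2 = two_n * f
        fst[:, j] = f
        pvals[:, j] = stats.chi2.sf(chi2, df=1)
        diffs[:, j] = freqs[:, j] - q_contrast

    valid = ~np.isnan(freqs).any(axis=1)
    sign = np.sign(diffs)
    e_sign = sign[:, e_idx]
    l_sign = sign[:, l_idx]
    dir_ok = (
        (np.abs(e_sign.sum(axis=1)) == 3)
        & (np.abs(l_sign.sum(axis=1)) == 3)
        & (e_sign[:, 0] == -l_sign[:, 0])
    )
    dir_ok &= valid
    direction = np.where(dir_ok, e_sign[:, 0], 0.0)
    max_p = np.where(valid, np.nanmax(pvals, axis=1), np.nan)
    return {
        "fst": fst,
        "p": pvals,
        "max_p": max_p,
        "direction_ok": dir_ok,
        "direction": direction,
        "valid": valid,
    }


def method1_test(
    freqs: Sequence[float] | np.ndarray,
    pools: Sequence[PoolSpec],
    p_level: float = 0.001,
) -> pd.DataFrame:
    """Six-comparison replicate F_ST test for one marker (or a matrix).

    Returns a tidy DataFrame with one row per (marker, focal pool):
    focal frequency, contrast-group mean, F_ST, chi-square, p-value and
    direction, plus a marker-level ``significant`` flag at ``p_level``
    (all six p <= P and directionally consistent).
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    res = method1_stats(freqs, pools)
    gam = np.array([p.n_gametes for p in pools], dtype=float)
    e_idx, l_idx = _split_pools(pools)
    rows = []
    for m in range(freqs.shape[0]):
        sig = bool(res["direction_ok"][m] and res["max_p"][m] <= p_level)
        for j, spec in enumerate(pools):
            contrast = l_idx if spec.group == EARLY else e_idx
            wc = gam[contrast]
            q_c = float(freqs[m, contrast] @ wc / wc.sum())
            two_n = gam[j] + wc.sum()
            rows.append(
                {
                    "marker": m,
                    "pool": spec.pool_id,
                    "q_focal": freqs[m, j],
                    "q_contrast": q_c,
                    "fst": res["fst"][m, j],
                    "two_n": two_n,
                    "chi2": two_n * res["fst"][m, j],
                    "p": res["p"][m, j],
                    "direction": np.sign(freqs[m, j] - q_c),
                    "marker_significant": sig,
                }
            )
    return pd.DataFrame(rows)


def method1_fdr(l: int, p_level: float, d: int) -> float:
    """FDR estimate for the six-fold directional test: (l P^3 / d)^2."""
    if d <= 0:
        return np.inf
    return (l * p_level**3 / d) ** 2


def method1_fdr_scan(
    max_p: np.ndarray,
    direction_ok: np.ndarray,
    p_grid: np.ndarray | None = None,
    target_fdr: float = 0.05,
) -> dict:
    """Scan P-levels and choose the largest with estimated FDR <= target.

    ``max_p`` is the worst of a marker's six per-pool p-values and
    ``direction_ok`` its direction-consistency flag; markers with NaN
    ``max_p`` are excluded from l.  Returns a dict with ``p_level``,
    ``fdr``, ``significant`` (boolean array over markers), ``d`` and ``l``;
    ``p_level`` is NaN and the set empty when no grid point satisfies the
    target with d > 0.
    """
    if p_grid is None:
        p_grid = DEFAULT_P_GRID
    p_grid = np.sort(np.asarray(p_grid, dtype=float))[::-1]
    if p_grid.size == 0:
        raise ValueError("empty P-grid")
    max_p = np.asarray(max_p, dtype=float)
    direction_ok = np.asarray(direction_ok, dtype=bool)
    tested = ~np.isnan(max_p)
    l = int(tested.sum())
    if l == 0:
        raise ValueError("no markers tested")
    for p_level in p_grid:
        sig = tested & direction_ok & (max_p <= p_level)
        d = int(sig.sum())
        fdr = method1_fdr(l, p_level, d)
        if d > 0 and fdr <= target_fdr:
            return {"p_level": float(p_level), "fdr": fdr, "significant": sig, "d": d, "l": l}
    warnings.warn("no P-level attains the target FDR; returning empty significant set")
    empty = np.zeros_like(tested, dtype=bool)
    return {"p_level": np.nan, "fdr": np.nan, "significant": empty, "d": 0, "l": l}


# ---------------------------------------------------------------------------
# Method 2: error-variance test
# ---------------------------------------------------------------------------

def method2_stats(
    freqs: np.ndarray,
    pools: Sequence[PoolSpec],
    n_ind: int = 52,
    n_rep: int = 3,
) -> dict[str, np.ndarray]:
    """Vectorised error-variance Z^2 test.

    Z^2 = (qbar_L - qbar_E)^2 / (V1_L + V1_E + V2_L + V2_E), chi^2(1).
    V1 = qbar(1-qbar)/(2 n_ind) per group; V2 = var(replicates, ddof=1)/n_rep.
    A zero denominator yields Z^2 = 0, p = 1 when the group means agree and
    Z^2 = inf, p = 0 (flagged ``degenerate``) when they differ.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    e_idx, l_idx = _split_pools(pools)
    gam = np.array([p.n_gametes for p in pools], dtype=float)

    out = {}
    for name, idx in (("early", e_idx), ("late", l_idx)):
        w = gam[idx]
        q = freqs[:, idx]
        qbar = q @ w / w.sum()
        v1 = qbar * (1.0 - qbar) / (2.0 * n_ind)
        v2 = np.var(q, axis=1, ddof=1) / n_rep
        out[f"qbar_{name}"] = qbar
        out[f"v1_{name}"] = v1
        out[f"v2_{name}"] = v2

    num = (out["qbar_late"] - out["qbar_early"]) ** 2
    den = out["v1_late"] + out["v1_early"] + out["v2_late"] + out["v2_early"]
    valid = ~np.isnan(freqs).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.where(num > 0, np.inf, 0.0))
    z2 = np.where(valid, z2, np.nan)
    p = np.where(np.isinf(z2), 0.0, stats.chi2.sf(np.where(np.isinf(z2), 0.0, z2), df=1))
    p = np.where(np.isnan(z2), np.nan, p)
    out.update(
        z2=z2,
        p=p,
        degenerate=valid & (den <= 0) & (num > 0),
        direction=np.where(valid, np.sign(out["qbar_early"] - out["qbar_late"]), 0.0),
        valid=valid,
    )
    return out


def method2_test(
    freqs: Sequence[float] | np.ndarray,
    pools: Sequence[PoolSpec],
    n_ind: int = 52,
    n_rep: int = 3,
) -> pd.DataFrame:
    """Error-variance test; one row per marker with qbar, V1, V2, Z^2, p."""
    res = method2_stats(np.atleast_2d(np.asarray(freqs, dtype=float)), pools, n_ind, n_rep)
    return pd.DataFrame(
        {
            "qbar_early": res["qbar_early"],
            "qbar_late": res["qbar_late"],
            "v1_early": res["v1_early"],
            "v1_late": res["v1_late"],
            "v2_early": res["v2_early"],
            "v2_late": res["v2_late"],
            "z2": res["z2"],
            "p": res["p"],
            "direction": res["direction"],
            "degenerate": res["degenerate"],
        }
    )


def method2_fdr(l: int, p_level: float, d: int) -> float:
    """Standard empirical FDR estimate l P / d."""
    if d <= 0:
        return np.inf
    return l * p_level / d


def method2_fdr_scan(
    p_values: np.ndarray,
    p_grid: np.ndarray | None = None,
    target_fdr: float = 0.05,
) -> dict:
    """Choose the largest P-level with l P / d(P) <= target FDR and d > 0."""
    if p_grid is None:
        p_grid = DEFAULT_P_GRID
    p_grid = np.sort(np.asarray(p_grid, dtype=float))[::-1]
    if p_grid.size == 0:
        raise ValueError("empty P-grid")
    p_values = np.asarray(p_values, dtype=float)
    tested = ~np.isnan(p_values)
    l = int(tested.sum())
    if l == 0:
        raise ValueError("no markers tested")
    for p_level in p_grid:
        sig = tested & (p_values <= p_level)
        d = int(sig.sum())
        fdr = method2_fdr(l, p_level, d)
        if d > 0 and fdr <= target_fdr:
            return {"p_level": float(p_level), "fdr": fdr, "significant": sig, "d": d, "l": l}
    warnings.warn("no P-level attains the target FDR; returning empty significant set")
    return {
        "p_level": np.nan,
        "fdr": np.nan,
        "significant": np.zeros_like(tested, dtype=bool),
        "d": 0,
        "l": l,
    }


# ---------------------------------------------------------------------------
# BayeScan interoperation
# ---------------------------------------------------------------------------

def export_bayescan(
    freqs: np.ndarray,
    pools: Sequence[PoolSpec],
    path,
    marker_ids: Sequence | None = None,
) -> list:
    """Write allele frequencies as a BayeScan 2.1 two-population input file.

    Per marker and phenotype group, frequencies are converted to absolute
    allele numbers: each replicate pool contributes 2 x n_individuals
    gametes (34 or 36), the reference-allele count per pool is
    round(q * gametes), and the three replicate pools of a group are summed
    (104 total by default).  Returns the marker manifest (ids in file order)
    used by :func:`import_bayescan` to map results back.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    e_idx, l_idx = _split_pools(pools)
    gam = np.array([p.n_gametes for p in pools], dtype=float)
    if marker_ids is None:
        marker_ids = list(range(freqs.shape[0]))
    manifest = list(marker_ids)

    lines = [f"[loci]={freqs.shape[0]}", "", "[populations]=2", ""]
    for pop_num, idx in ((1, e_idx), (2, l_idx)):
        lines.append(f"[pop]={pop_num}")
        total = int(gam[idx].sum())
        for m in range(freqs.shape[0]):
            ref = int(np.round(freqs[m, idx] * gam[idx]).sum())
            if ref > total:
                warnings.warn(f"marker {manifest[m]}: rounded count exceeds total; clamped")
                ref = total
            ref = max(ref, 0)
            lines.append(f"{m + 1} {total} 2 {ref} {total - ref}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return manifest


def import_bayescan(path, q_threshold: float = 0.05, manifest: Sequence | None = None) -> set:
    """Read a BayeScan ``*_fst.txt`` result table; return significant markers.

    Rows are mapped back to marker ids by line order against the export
    manifest (or kept as 0-based row indices when no manifest is given).
    Markers with q-value <= ``q_threshold`` are returned.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.empty:
        return set()
    qcol = next((c for c in df.columns if c.lower() in {"qval", "q_value", "qvalue"}), None)
    if qcol is None:
        raise ValueError(f"no q-value column found in {path}; columns: {list(df.columns)}")
    if manifest is not None and len(manifest) != len(df):
        raise ValueError(
            f"BayeScan results have {len(df)} rows but the export manifest has "
            f"{len(manifest)} markers"
        )
    hits = np.flatnonzero(df[qcol].to_numpy(dtype=float) <= q_threshold)
    if manifest is None:
        return set(int(i) for i in hits)
    return {manifest[i] for i in hits}


def intersect_methods(method_sets: Mapping[str, Iterable]) -> dict:
    """Intersect significant-marker sets across methods.

    Returns a dict with the ``consensus`` set and per-method counts.
    """
    sets = {name: set(s) for name, s in method_sets.items()}
    if not sets:
        return {"consensus": set(), "per_method": {}}
    consensus = set.intersection(*sets.values())
    return {
        "consensus": consensus,
        "per_method": {name: len(s) for name, s in sets.items()},
    }


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class PoolContrast:
    """Differentiation model for a two-extreme replicate-pool experiment.

    Parameters
    ----------
    freqs : DataFrame (markers x pools)
        Allele frequency of each marker in each pool; columns must match the
        ``pool_id`` of ``pools``.  For SNPs this is the reference-allele
        frequency; haplotype variants enter one-vs-rest as pseudo-biallelic
        frequencies.
    pools : six PoolSpec (3 early + 3 late)

    Examples
    --------
    >>> model = PoolContrast.from_raf_table(raf_df, pools)   # doctest: +SKIP
    >>> res = model.fit(method="fst_replicate", fdr=0.05)    # doctest: +SKIP
    >>> print(res.summary())                                 # doctest: +SKIP
    """

    def __init__(self, freqs: pd.DataFrame, pools: Sequence[PoolSpec]):
        self.pools = list(pools)
        cols = [p.pool_id for p in self.pools]
        missing = [c for c in cols if c not in freqs.columns]
        if missing:
            raise ValueError(f"frequency table lacks pool columns {missing}")
        self.freqs = freqs[cols].astype(float)
        self.marker_ids = list(freqs.index)

    @classmethod
    def from_raf_table(cls, raf: pd.DataFrame, pools: Sequence[PoolSpec]) -> "PoolContrast":
        """Build from a wide RAF table (``{pool}_raf`` columns; see io)."""
        data = {p.pool_id: raf[f"{p.pool_id}_raf"].to_numpy(dtype=float) for p in pools}
        idx = raf.index
        if {"chrom", "pos"}.issubset(raf.columns):
            idx = pd.Index(
                [f"{c}:{p}" for c, p in zip(raf["chrom"], raf["pos"])], name="marker"
            )
        return cls(pd.DataFrame(data, index=idx), pools)

    @classmethod
    def from_htp_table(cls, htp: pd.DataFrame, pools: Sequence[PoolSpec]) -> "PoolContrast":
        """Build from a haplotype table, one-vs-rest per variant.

        Each (locus, haplotype) row becomes a pseudo-biallelic marker whose
        frequency is the variant's relative frequency in the pool.
        """
        data = {p.pool_id: htp[f"{p.pool_id}_freq"].to_numpy(dtype=float) for p in pools}
        idx = pd.Index(
            [f"{l}|{h}" for l, h in zip(htp["locus_id"], htp["haplotype"])], name="marker"
        )
        return cls(pd.DataFrame(data, index=idx), pools)

    def fit(
        self,
        method: str = "fst_replicate",
        fdr: float = 0.05,
        p_grid: np.ndarray | None = None,
        n_ind: int = 52,
        n_rep: int = 3,
    ) -> "ContrastResults":
        """Run one test across all markers and calibrate its P-level by FDR.

        ``method`` is ``"fst_replicate"`` (six-comparison F_ST test) or
        ``"error_variance"`` (Z^2 test).
        """
        X = self.freqs.to_numpy(dtype=float)
        if method == "fst_replicate":
            st = method1_stats(X, self.pools)
            scan = method1_fdr_scan(st["max_p"], st["direction_ok"], p_grid, fdr)
            table = pd.DataFrame(
                {
                    "p": st["max_p"],
                    "direction_ok": st["direction_ok"],
                    "direction": st["direction"],
                    "max_fst": np.nanmax(st["fst"], axis=1),
                },
                index=self.freqs.index,
            )
        elif method == "error_variance":
            st = method2_stats(X, self.pools, n_ind=n_ind, n_rep=n_rep)
            scan = method2_fdr_scan(st["p"], p_grid, fdr)
            table = pd.DataFrame(
                {
                    "p": st["p"],
                    "z2": st["z2"],
                    "direction": st["direction"],
                    "qbar_early": st["qbar_early"],
                    "qbar_late": st["qbar_late"],
                },
                index=self.freqs.index,
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        table["significant"] = scan["significant"]
        return ContrastResults(
            model=self,
            method=method,
            table=table,
            p_level=scan["p_level"],
            fdr_estimate=scan["fdr"],
            target_fdr=fdr,
            n_tested=scan["l"],
            n_significant=scan["d"],
        )


@dataclass
class ContrastResults:
    """Fitted differentiation-test results for one method.

    Attributes
    ----------
    table : DataFrame
        Per-marker statistics, p-values and the ``significant`` flag at the
        FDR-calibrated P-level.
    p_level : float
        Chosen per-test significance level (NaN if none attained the FDR).
    fdr_estimate : float
        Estimated FDR at ``p_level``.
    """

    model: PoolContrast
    method: str
    table: pd.DataFrame
    p_level: float
    fdr_estimate: float
    target_fdr: float
    n_tested: int
    n_significant: int

    @property
    def significant(self) -> set:
        return set(self.table.index[self.table["significant"]])

    def two_group_fst(self) -> pd.Series:
        """Per-marker early-vs-late aggregate F_ST (reporting summary)."""
        e_idx, l_idx = _split_pools(self.model.pools)
        gam = np.array([p.n_gametes for p in self.model.pools], dtype=float)
        X = self.model.freqs.to_numpy(dtype=float)
        qe = X[:, e_idx] @ gam[e_idx] / gam[e_idx].sum()
        ql = X[:, l_idx] @ gam[l_idx] / gam[l_idx].sum()
        return pd.Series(_fst_arrays(qe, ql, 1.0, 1.0), index=self.model.freqs.index)

    def summary(self) -> str:
        buf = io.StringIO()
        name = {
            "fst_replicate": "Replicate F_ST test (six comparisons, direction rule)",
            "error_variance": "Error-variance Z^2 test",
        }[self.method]
        buf.write(f"{name}\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"Markers tested (l):        {self.n_tested}\n")
        buf.write(f"Target FDR:                {self.target_fdr:g}\n")
        if np.isnan(self.p_level):
            buf.write("Chosen P-level:            none (no level met the target FDR)\n")
        else:
            buf.write(f"Chosen P-level:            {self.p_level:.3g}\n")
            buf.write(f"Estimated FDR at P:        {self.fdr_estimate:.3g}\n")
        buf.write(f"Significant markers (d):   {self.n_significant}\n")
        sig = self.table[self.table["significant"]]
        if len(sig):
            buf.write("-" * 60 + "\n")
            buf.write(sig.to_string(max_rows=30, float_format=lambda v: f"{v:.4g}"))
            buf.write("\n")
        return buf.getvalue()
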