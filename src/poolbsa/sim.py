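"""Forward simulation of a pooled extreme-phenotype GBS experiment.

The generator emulates the statistical structure the downstream analysis
assumes: an outbreeding population in Hardy-Weinberg proportions, a
quantitative days-to-elongation (DTE) trait controlled by a handful of
planted QTLs plus Gaussian noise, right-censoring of individuals that never
elongate within the observation window, truncation selection of the two
phenotypic extremes, random partitioning of each extreme group into
replicate DNA pools, and depth-limited sequencing of each pool producing
a SNP reference-allele-frequency (RAF) table with allele-presence
posteriors and a multi-allelic haplotype-locus table, alongside a ground
truth table of per-pool and per-group allele frequencies.

Read depth per marker and pool follows a negative binomial; read counts
are binomial in the pool's true allele frequency perturbed by a per-read
substitution error.  Haplotype loci are formed by grouping k consecutive
SNPs; within a pool, variant probabilities assume linkage equilibrium
between the grouped SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pools import EARLY, LATE, PoolSpec, _split_sizes

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class TraitModel:
    """Additive quantitative-trait model for days to elongation (DTE).

    Parameters
    ----------
    qtl_markers : list of int
        Indices of causal markers in the founder panel.
    qtl_effects : list of float
        Additive effect, in days per alternative-allele copy.
    baseline_dte : float
        Expected DTE of an individual with zero alternative dosage at all
        QTLs, days.
    noise_sd : float
        Environmental (non-genetic) standard deviation, days.
    censor_day : float
        Individuals whose DTE exceeds this day are "non-elongating" and
        excluded from selection.
    """

    qtl_markers: list = field(default_factory=list)
    qtl_effects: list = field(default_factory=list)
    baseline_dte: float = 82.0
    noise_sd: float = 10.0
    censor_day: float = 94.0

    def __post_init__(self) -> None:
        if len(self.qtl_markers) != len(self.qtl_effects):
            raise ValueError("one effect per QTL marker required")
        if len(set(self.qtl_markers)) != len(self.qtl_markers):
            raise ValueError("QTL marker indices must be distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.censor_day <= self.baseline_dte:
            raise ValueError("censor_day must exceed baseline_dte")


@dataclass
class FounderPanel:
    """Marker panel describing founder diversity.

    ``alt_freqs`` is the frequency of the alternative allele among founder
    gametes; positions are 1-based and strictly increasing per chromosome.
    """

    chroms: np.ndarray
    positions: np.ndarray
    alt_freqs: np.ndarray
    ref_bases: np.ndarray | None = None
    alt_bases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alt_freqs = np.asarray(self.alt_freqs, dtype=float)
        if not ((self.alt_freqs >= 0) & (self.alt_freqs <= 1)).all():
            raise ValueError("founder allele frequencies must lie in [0, 1]")
        for c in np.unique(self.chroms):
            pos = self.positions[self.chroms == c]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions must strictly increase within chromosome {c}")
        if self.ref_bases is None:
            self.ref_bases = np.full(self.n_markers, "A")
        if self.alt_bases is None:
            self.alt_bases = np.full(self.n_markers, "G")

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    @classmethod
    def random(
        cls,
        n_markers: int,
        n_chrom: int = 7,
        chrom_length: int = 30_000_000,
        freq_range: tuple[float, float] = (0.05, 0.95),
        unplaced_fraction: float = 0.0,
        seed: int | np.random.Generator = 0,
    ) -> "FounderPanel":
        """Random panel: markers spread uniformly over ``n_chrom``
        chromosomes (an optional fraction on unplaced scaffolds), founder
        alternative-allele frequencies uniform in ``freq_range``."""
        rng = np.random.default_rng(seed)
        chrom_ids = rng.integers(1, n_chrom + 1, size=n_markers)
        n_unplaced = int(round(unplaced_fraction * n_markers))
        if n_unplaced:
            idx = rng.choice(n_markers, size=n_unplaced, replace=False)
            chrom_labels = chrom_ids.astype(object)
            for k, i in enumerate(idx):
                chrom_labels[i] = f"scaffold_{k + 1}"
        else:
            chrom_labels = chrom_ids.astype(object)
        # strictly increasing positions within each chromosome label
        positions = np.empty(n_markers, dtype=np.int64)
        for c in np.unique(chrom_labels.astype(str)):
            mask = chrom_labels.astype(str) == c
            m = int(mask.sum())
            pos = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=m, replace=False))
            positions[mask] = pos
        freqs = rng.uniform(*freq_range, size=n_markers)
        ref = BASES[rng.integers(0, 4, size=n_markers)]
        alt = np.array(
            [BASES[np.flatnonzero(BASES != r)[rng.integers(0, 3)]] for r in ref]
        )
        return cls(chrom_labels, positions, freqs, ref, alt)


@dataclass
class Population:
    """Simulated diploid individuals with DTE phenotypes."""

    dosages: np.ndarray  # (n_individuals, n_markers) alt-allele dosage 0/1/2
    dte: np.ndarray
    elongating: np.ndarray  # bool mask; False = censored (non-elongating)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]


def simulate_population(
    panel: FounderPanel,
    n_individuals: int,
    trait: TraitModel,
    seed: int | np.random.Generator = 0,
    ld_block_size: int | None = None,
) -> Population:
    """Draw a Hardy-Weinberg population and its DTE phenotypes.

    With ``ld_block_size`` set, gamete alleles are drawn from a shared
    uniform per block of that many consecutive markers, inducing strong
    positive within-block linkage disequilibrium; by default markers are
    independent (free recombination), which matches single-marker tests.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    for q in trait.qtl_markers:
        if not (0 <= q < panel.n_markers):
            raise ValueError(f"QTL marker index {q} out of range for panel")
    rng = np.random.default_rng(seed)
    q = panel.alt_freqs
    if ld_block_size is None:
        dosages = rng.binomial(2, q, size=(n_individuals, panel.n_markers)).astype(np.uint8)
    else:
        block = np.arange(panel.n_markers) // ld_block_size
        n_blocks = block.max() + 1
        dosages = np.zeros((n_individuals, panel.n_markers), dtype=np.uint8)
        for gamete in range(2):
            u = rng.random(size=(n_individuals, n_blocks))
            dosages += (u[:, block] < q).astype(np.uint8)
    dte = np.full(n_individuals, trait.baseline_dte, dtype=float)
    if trait.qtl_markers:
        eff = np.asarray(trait.qtl_effects, dtype=float)
        dte += dosages[:, np.asarray(trait.qtl_markers, dtype=int)] @ eff
    if trait.noise_sd > 0:
        dte += rng.normal(0.0, trait.noise_sd, size=n_individuals)
    return Population(dosages=dosages, dte=dte, elongating=dte <= trait.censor_day)


def select_extremes(pop: Population, n_select: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``n_select`` earliest and latest elongating individuals.

    Ties in DTE are broken by individual index (stable sort); the two groups
    are always disjoint.
    """
    idx = np.flatnonzero(pop.elongating)
    if len(idx) < 2 * n_select:
        raise ValueError(
            f"need at least {2 * n_select} elongating individuals, have {len(idx)}"
        )
    order = idx[np.argsort(pop.dte[idx], kind="stable")]
    early = order[:n_select]
    late = order[-n_select:]
    return early, late


def make_pools(
    members: np.ndarray,
    group: str,
    n_pools: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[PoolSpec, np.ndarray]]:
    """Randomly partition a selected group into replicate pools.

    Pool sizes differ by at most one (52 into 3 -> 18, 17, 17); each
    individual lands in exactly one pool.  Deterministic for a fixed seed.
    """
    members = np.asarray(members)
    sizes = _split_sizes(len(members), n_pools)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(members)
    out = []
    start = 0
    for rep, size in enumerate(sizes, start=1):
        spec = PoolSpec(group=group, replicate=rep, n_individuals=size)
        out.append((spec, np.sort(perm[start : start + size])))
        start += size
    return out


def _presence_posterior(count: np.ndarray, depth: np.ndarray, error_rate: float) -> np.ndarray:
    """1 - P(observing >= count reads of the allele under its absence).

    Under absence the allele's reads arise only from sequencing error, so
    the posterior proxy is the binomial CDF at count-1 with p = error rate;
    zero observed reads give posterior 0, many reads give ~1.
    """
    with np.errstate(invalid="ignore"):
        post = stats.binom.cdf(count - 1, depth, error_rate)
    post = np.where(depth > 0, post, 0.0)
    return np.clip(post, 0.0, 1.0)


def sequence_pools(
    pop: Population,
    pools: list[tuple[PoolSpec, np.ndarray]],
    panel: FounderPanel,
    depth_mean: float = 100.0,
    depth_dispersion: float = 5.0,
    min_depth: int = 0,
    error_rate: float = 0.001,
    haplotype_k: int = 2,
    trait: TraitModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sequence each pool: emit RAF, haplotype and truth tables.

    Depth per (marker, pool) is negative binomial with the given mean and
    dispersion (variance mean + mean^2/dispersion), floored at ``min_depth``
    (use the floor to emulate post-filter data).  Alternative-allele reads
    are binomial with success probability q(1-e) + (1-q)e where q is the
    pool's true alternative-allele frequency and e the per-read error.
    RAF = ref / (ref + alt); presence posteriors come from a binomial
    absence model.  Haplotype loci group ``haplotype_k`` consecutive SNPs
    on a chromosome into 0/1 strings with multinomial per-pool counts;
    ``haplotype_k=0`` skips the haplotype table (empty frame returned).
    """
    if depth_mean <= 0:
        raise ValueError("depth mean must be positive")
    if not (0.0 <= error_rate <= 0.1):
        raise ValueError("error_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    n_pools = len(pools)
    m = panel.n_markers

    true_q = np.empty((n_pools, m))
    for i, (_, members) in enumerate(pools):
        true_q[i] = pop.dosages[members].mean(axis=0) / 2.0

    nb_p = depth_dispersion / (depth_dispersion + depth_mean)
    depth = rng.negative_binomial(depth_dispersion, nb_p, size=(n_pools, m))
    if min_depth > 0:
        depth = np.maximum(depth, min_depth)

    p_alt_read = true_q * (1.0 - error_rate) + (1.0 - true_q) * error_rate
    alt = rng.binomial(depth, p_alt_read)
    ref = depth - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        raf = np.where(depth > 0, ref / np.where(depth > 0, depth, 1), np.nan)

    raf_df = pd.DataFrame(
        {
            "chrom": panel.chroms.astype(str),
            "pos": panel.positions,
            "ref": panel.ref_bases,
            "alt": panel.alt_bases,
        }
    )
    for i, (spec, _) in enumerate(pools):
        pid = spec.pool_id
        raf_df[f"{pid}_ref_count"] = ref[i]
        raf_df[f"{pid}_alt_count"] = alt[i]
        raf_df[f"{pid}_raf"] = raf[i]
        raf_df[f"{pid}_p_ref"] = _presence_posterior(ref[i], depth[i], error_rate)
        raf_df[f"{pid}_p_alt"] = _presence_posterior(alt[i], depth[i], error_rate)

    if haplotype_k > 0:
        htp_df = _haplotype_table(panel, true_q, pools, haplotype_k, depth_mean,
                                  depth_dispersion, min_depth, rng)
    else:
        htp_df = pd.DataFrame(
            columns=["locus_id", "chrom", "start", "end", "haplotype"]
            + [f"{spec.pool_id}_{s}" for spec, _ in pools for s in ("count", "freq")]
        )

    truth = pd.DataFrame(
        {
            "marker_id": [f"{c}:{p}" for c, p in zip(panel.chroms.astype(str), panel.positions)],
            "chrom": panel.chroms.astype(str),
            "pos": panel.positions,
            "is_qtl": False,
            "effect": 0.0,
        }
    )
    if trait is not None and trait.qtl_markers:
        qi = np.asarray(trait.qtl_markers, dtype=int)
        truth.loc[qi, "is_qtl"] = True
        truth.loc[qi, "effect"] = np.asarray(trait.qtl_effects, dtype=float)
    for i, (spec, _) in enumerate(pools):
        truth[f"{spec.pool_id}_true_freq"] = true_q[i]
    for group in (EARLY, LATE):
        members = np.concatenate(
            [mem for spec, mem in pools if spec.group == group]
        ) if any(spec.group == group for spec, _ in pools) else np.array([], dtype=int)
        if len(members):
            truth[f"{group}_true_freq"] = pop.dosages[members].mean(axis=0) / 2.0
    return raf_df, htp_df, truth


def _haplotype_table(panel, true_q, pools, k, depth_mean, depth_dispersion,
                     min_depth, rng) -> pd.DataFrame:
    """Group k consecutive SNPs per chromosome into haplotype loci."""
    rows = []
    chrom_str = panel.chroms.astype(str)
    variants = [format(v, f"0{k}b") for v in range(2**k)]
    bits = np.array([[int(ch) for ch in s] for s in variants])  # (2^k, k)
    nb_p = depth_dispersion / (depth_dispersion + depth_mean)
    for c in pd.unique(chrom_str):
        idx = np.flatnonzero(chrom_str == c)
        for start in range(0, len(idx) - k + 1, k):
            grp = idx[start : start + k]
            locus_id = f"htp_{c}_{panel.positions[grp[0]]}"
            # per pool: P(variant) under within-pool linkage equilibrium
            q = true_q[:, grp]  # (n_pools, k)
            probs = np.prod(
                np.where(bits[None, :, :] == 1, q[:, None, :], 1.0 - q[:, None, :]),
                axis=2,
            )  # (n_pools, 2^k)
            depth = rng.negative_binomial(depth_dispersion, nb_p, size=len(pools))
            if min_depth > 0:
                depth = np.maximum(depth, min_depth)
            counts = np.vstack(
                [rng.multinomial(depth[i], probs[i]) for i in range(len(pools))]
            )  # (n_pools, 2^k)
            seen = counts.sum(axis=0) > 0
            for v in np.flatnonzero(seen):
                row = {
                    "locus_id": locus_id,
                    "chrom": c,
                    "start": int(panel.positions[grp[0]]),
                    "end": int(panel.positions[grp[-1]]),
                    "haplotype": variants[v],
                }
                for i, (spec, _) in enumerate(pools):
                    tot = counts[i].sum()
                    row[f"{spec.pool_id}_count"] = int(counts[i, v])
                    row[f"{spec.pool_id}_freq"] = counts[i, v] / tot if tot > 0 else 0.0
                rows.append(row)
    cols = ["locus_id", "chrom", "start", "end", "haplotype"] + [
        f"{spec.pool_id}_{s}" for spec, _ in pools for s in ("count", "freq")
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_annotation(
    marker_positions: list[tuple[str, int]],
    path,
    genes_per_window: int = 2,
    genes_outside: int = 2,
    flank: int = 50_000,
    gene_length: int = 2_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Write a toy GFF3 with genes planted inside and outside marker windows.

    For each (chrom, pos) marker, ``genes_per_window`` genes are placed so
    that they overlap the +/- ``flank`` window (inclusive) and
    ``genes_outside`` genes are placed safely beyond it.  Returns the truth
    table (gene_id, chrom, start, end, in_window, nearest marker).
    """
    rng = np.random.default_rng(seed)
    rows = []
    gff_lines = ["##gff-version 3"]
    gid = 0
    for chrom, pos in marker_positions:
        lo, hi = max(1, pos - flank), pos + flank
        for _ in range(genes_per_window):
            gid += 1
            start = int(rng.integers(lo, hi + 1))
            end = start + gene_length - 1
            rows.append(dict(gene_id=f"gene{gid}", chrom=str(chrom), start=start,
                             end=end, in_window=True, marker_pos=pos))
        for _ in range(genes_outside):
            gid += 1
            offset = int(rng.integers(flank + gene_length + 1, flank + 10 * gene_length))
            side = 1 if rng.random() < 0.5 else -1
            start = max(1, pos + side * offset)
            if side < 0:
                start = max(1, pos - offset - gene_length)
            end = start + gene_length - 1
            in_win = start <= hi and end >= lo
            rows.append(dict(gene_id=f"gene{gid}", chrom=str(chrom), start=start,
                             end=end, in_window=in_win, marker_pos=pos))
    truth = pd.DataFrame(rows)
    for r in truth.itertuples():
        strand = "+" if r.Index % 2 == 0 else "-"
        gff_lines.append(
            f"{r.chrom}\tpoolbsa_sim\tgene\t{r.start}\t{r.end}\t.\t{strand}\t.\tID={r.gene_id}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    return truth
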