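"""Pool design: which individuals went into which sequenced DNA pool.

The default design mirrors a two-extreme selective-genotyping experiment:
each phenotype group of 52 selected individuals is split at random into
three replicate pools of 17-18 individuals, so each pool represents
34 or 36 gametes (haploid genomes) of the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EARLY = "early"
LATE = "late"
GROUPS = (EARLY, LATE)


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced DNA pool.

    Parameters
    ----------
    group : str
        Phenotype group, ``"early"`` or ``"late"``.
    replicate : int
        Replicate index within the group (1-based).
    n_individuals : int
        Number of diploid individuals pooled.
    """

    group: str
    replicate: int
    n_individuals: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based")
        if self.n_individuals < 1:
            raise ValueError("pool must contain at least one individual")

    @property
    def n_gametes(self) -> int:
        """Haploid genomes represented by the pool (2 per diploid)."""
        return 2 * self.n_individuals

    @property
    def pool_id(self) -> str:
        return f"{'E' if self.group == EARLY else 'L'}{self.replicate}"


def default_design(n_select: int = 52, n_pools: int = 3) -> list[PoolSpec]:
    """Six pools: per group, ``n_select`` individuals in ``n_pools`` replicate
    pools whose sizes differ by at most one (52 -> 18, 17, 17)."""
    sizes = _split_sizes(n_select, n_pools)
    specs = []
    for group in GROUPS:
        for rep, size in enumerate(sizes, start=1):
            specs.append(PoolSpec(group=group, replicate=rep, n_individuals=size))
    return specs


def _split_sizes(n: int, k: int) -> list[int]:
    if k < 1 or k > n:
        raise ValueError(f"cannot split {n} individuals into {k} pools")
    base, extra = divmod(n, k)
    return [base + 1] * extra + [base] * (k - extra)
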