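import numpy as np
import pandas as pd
import pytest

from poolbsa.pools import EARLY, LATE, PoolSpec, default_design

POOL_IDS = ["E1", "E2", "E3", "L1", "L2", "L3"]


@pytest.fixture(scope="session")
def pools() -> list[PoolSpec]:
    return default_design()


def make_raf_row(
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    raf=0.5,
    depth=100,
    p_ref=1.0,
    p_alt=1.0,
    **overrides,
):
    """One wide RAF-table row with identical pool values unless overridden.

    Per-pool overrides use keys like ``E1_raf`` or ``L2_depth``; counts are
    derived from raf and depth.
    """
    row = {"chrom": str(chrom), "pos": pos, "ref": ref, "alt": alt}
    for pid in POOL_IDS:
        r = overrides.get(f"{pid}_raf", raf)
        d = overrides.get(f"{pid}_depth", depth)
        row[f"{pid}_ref_count"] = int(round(r * d))
        row[f"{pid}_alt_count"] = d - int(round(r * d))
        row[f"{pid}_raf"] = r
        row[f"{pid}_p_ref"] = overrides.get(f"{pid}_p_ref", p_ref)
        row[f"{pid}_p_alt"] = overrides.get(f"{pid}_p_alt", p_alt)
    for key, val in overrides.items():
        if key in row or any(
            key.endswith(s) for s in ("_ref_count", "_alt_count", "_both_nonref", "_alt_base")
        ):
            row[key] = val
    return row


def make_htp_rows(locus_id, chrom, start, end, variants, counts):
    """Haplotype-table rows for one locus.

    ``variants`` is a list of haplotype strings; ``counts`` a dict
    pool_id -> list of per-variant read counts.
    """
    rows = []
    for vi, hap in enumerate(variants):
        row = {
            "locus_id": locus_id,
            "chrom": str(chrom),
            "start": start,
            "end": end,
            "haplotype": hap,
        }
        for pid in POOL_IDS:
            c = counts[pid][vi]
            tot = sum(counts[pid])
            row[f"{pid}_count"] = c
            row[f"{pid}_freq"] = c / tot if tot else 0.0
        rows.append(row)
    return rows


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
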