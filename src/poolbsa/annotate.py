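"""Locus naming, marker clustering and flanking-gene extraction.

Significant markers are grouped into loci by single-linkage clustering
along the chromosome, each locus is named ``<chrom>_<Mb>`` with the
megabase position rounded half-up to two decimals, and candidate genes are
collected from a GFF3 annotation within a +/- 50 kb window around the
locus' marker span (1-based inclusive overlap).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import gffutils
import pandas as pd


def locus_name(chrom, pos: int) -> str:
    """Locus label ``<chromosome>_<position in Mb, 2 dp, half-up>``.

    Unplaced scaffolds are labelled ``scaffold:<id>_<pos>``.
    """
    if pos < 1:
        raise ValueError("positions are 1-based")
    chrom_str = str(chrom)
    if not re.fullmatch(r"\d+", chrom_str):
        return f"scaffold:{chrom_str}_{pos}"
    mb = (Decimal(int(pos)) / Decimal(1_000_000)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{chrom_str}_{mb}"


@dataclass
class Locus:
    """A cluster of nearby significant markers on one chromosome."""

    chrom: str
    anchors: list  # marker positions (sorted)
    marker_ids: list = field(default_factory=list)

    @property
    def name(self) -> str:
        return locus_name(self.chrom, self.anchors[0])

    def window(self, flank: int = 50_000) -> tuple[int, int]:
        return max(1, min(self.anchors) - flank), max(self.anchors) + flank


@dataclass
class LocusReport:
    """Genes found in the flanking window of one locus."""

    locus: Locus
    flank: int
    genes: pd.DataFrame  # gene_id, start, end, strand, distance

    @property
    def window(self) -> tuple[int, int]:
        return self.locus.window(self.flank)

    def to_frame(self) -> pd.DataFrame:
        df = self.genes.copy()
        df.insert(0, "locus", self.locus.name)
        if "chrom" not in df.columns:
            df.insert(1, "chrom", self.locus.chrom)
        return df


def cluster_markers(markers: pd.DataFrame, join_distance: int = 100_000) -> list[Locus]:
    """Single-linkage clustering of markers within ``join_distance`` bp.

    ``markers`` needs ``chrom`` and ``pos`` columns (optionally
    ``marker_id``); markers on one chromosome whose neighbour gaps are all
    <= ``join_distance`` merge into one locus, named by its first marker.
    """
    loci: list[Locus] = []
    df = markers.sort_values(["chrom", "pos"], kind="stable")
    ids = df["marker_id"] if "marker_id" in df.columns else df.index.to_series()
    for chrom, sub in df.groupby("chrom", sort=True):
        positions = sub["pos"].to_numpy()
        sub_ids = list(ids.loc[sub.index])
        current = Locus(chrom=str(chrom), anchors=[int(positions[0])],
                        marker_ids=[sub_ids[0]])
        for p, mid in zip(positions[1:], sub_ids[1:]):
            if p - current.anchors[-1] <= join_distance:
                current.anchors.append(int(p))
                current.marker_ids.append(mid)
            else:
                loci.append(current)
                current = Locus(chrom=str(chrom), anchors=[int(p)], marker_ids=[mid])
        loci.append(current)
    return loci


def _load_genes(gff3) -> pd.DataFrame:
    """All ``gene`` features of a GFF3 file as a DataFrame."""
    db = gffutils.create_db(
        str(gff3), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {"gene_id": gene_id, "chrom": str(feat.seqid), "start": feat.start,
             "end": feat.end, "strand": feat.strand}
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def flanking_genes(locus: Locus, gff3, flank: int = 50_000) -> LocusReport:
    """Genes overlapping the locus' +/- ``flank`` window (inclusive).

    Genes are sorted by distance to the nearest anchor marker (0 when a
    gene covers an anchor).  An absent chromosome yields an empty list with
    a warning.
    """
    genes = _load_genes(gff3) if not isinstance(gff3, pd.DataFrame) else gff3
    lo, hi = locus.window(flank)
    sub = genes[genes["chrom"] == locus.chrom]
    if sub.empty and locus.chrom not in set(genes["chrom"]):
        warnings.warn(f"chromosome {locus.chrom} absent from annotation")
    hit = sub[(sub["start"] <= hi) & (sub["end"] >= lo)].copy()
    if len(hit):
        anchors = locus.anchors
        hit["distance"] = [
            min(
                0 if g.start <= a <= g.end else min(abs(g.start - a), abs(g.end - a))
                for a in anchors
            )
            for g in hit.itertuples()
        ]
        hit = hit.sort_values(["distance", "start"], kind="stable").reset_index(drop=True)
    else:
        hit["distance"] = pd.Series(dtype=int)
    return LocusReport(locus=locus, flank=flank, genes=hit.reset_index(drop=True))


def windows_to_bed(loci: list[Locus], flank: int = 50_000) -> pd.DataFrame:
    """Locus windows as 0-based half-open BED intervals."""
    rows = []
    for loc in loci:
        lo, hi = loc.window(flank)
        rows.append({"chrom": loc.chrom, "start": lo - 1, "end": hi, "name": loc.name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
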