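"""Regulatory-window SNP selection.

Gene coding intervals are expanded 2 kb upstream and 1 kb downstream
(strand-aware by default) and intersected with variant positions to pick
the loci used as model features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from autogs.genotype_io import VariantTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding interval: 1-based inclusive coordinates."""

    id: str
    chrom: str
    cds_start: int
    cds_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValueError(f"gene {self.id}: cds_start > cds_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class RegulatoryWindow:
    """Expanded interval around a gene, 1-based inclusive."""

    gene_id: str
    chrom: str
    win_start: int
    win_end: int


def load_genes(path, format: str | None = None, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models from GFF3 or BED.

    BED intervals (0-based half-open) are converted to 1-based inclusive.
    The format is inferred from the file extension when not given.
    Duplicate gene ids are rejected.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        if lower.endswith((".gff", ".gff3")):
            format = "gff3"
        elif lower.endswith(".bed"):
            format = "bed"
        else:
            raise ValueError(f"cannot infer gene-file format from {path!r}; pass format=")
    if format == "bed":
        genes = _load_bed(path)
    elif format == "gff3":
        genes = _load_gff3(path, feature_type)
    else:
        raise ValueError(f"unknown gene-file format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.id in seen:
            raise ValueError(f"duplicate gene id {g.id!r} in {path!r}")
        seen.add(g.id)
    return genes


def _load_bed(path: str) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneModel(
            id=str(r["name"]),
            chrom=str(r["chrom"]),
            cds_start=int(r["start"]) + 1,
            cds_end=int(r["end"]),
            strand=str(r["strand"]),
        )
        for _, r in df.iterrows()
    ]


def _load_gff3(path: str, feature_type: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                id=gid,
                chrom=feat.seqid,
                cds_start=feat.start,
                cds_end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def expand_window(
    g: GeneModel, up: int = 2000, down: int = 1000, *, strand_aware: bool = True
) -> RegulatoryWindow:
    """Expand a gene interval ``up`` bases upstream and ``down`` downstream.

    Upstream/downstream follow the gene's strand when ``strand_aware``;
    otherwise upstream is always to the left.  The window is clipped at
    position 1.
    """
    if up < 0 or down < 0:
        raise ValueError("up and down must be >= 0")
    if strand_aware and g.strand == "-":
        left, right = down, up
    else:
        left, right = up, down
    return RegulatoryWindow(
        gene_id=g.id,
        chrom=g.chrom,
        win_start=max(1, g.cds_start - left),
        win_end=g.cds_end + right,
    )


def select_snps(vt: VariantTable, windows: list[RegulatoryWindow]) -> np.ndarray:
    """Indices of loci falling inside at least one window, order preserved.

    Logs a warning with per-chromosome counts when the variant table and
    the windows share no chromosome names.
    """
    d = vt.df
    if not len(d) or not windows:
        return np.zeros(0, dtype=int)
    win_chroms = {w.chrom for w in windows}
    vt_chroms = set(d["chrom"])
    if not (win_chroms & vt_chroms):
        logger.warning(
            "select_snps: no chromosome overlap between variants %s and windows %s",
            {c: int((d["chrom"] == c).sum()) for c in sorted(vt_chroms)},
            {c: sum(w.chrom == c for w in windows) for c in sorted(win_chroms)},
        )
    selected = np.zeros(len(d), dtype=bool)
    pos = d["pos"].to_numpy(dtype=np.int64)
    chrom_arr = d["chrom"].to_numpy()
    for chrom in sorted(win_chroms & vt_chroms):
        starts = np.array([w.win_start for w in windows if w.chrom == chrom], dtype=np.int64)
        ends = np.array([w.win_end for w in windows if w.chrom == chrom], dtype=np.int64)
        # coverage sweep: +1 at start, -1 past end; position covered iff
        # prefix-sum of events at or before it is positive
        bounds = np.concatenate([starts, ends + 1])
        deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
        order = np.argsort(bounds, kind="stable")
        bounds, deltas = bounds[order], deltas[order]
        coverage = np.cumsum(deltas)
        row = chrom_arr == chrom
        idx = np.searchsorted(bounds, pos[row], side="right") - 1
        cov = np.where(idx >= 0, coverage[np.clip(idx, 0, None)], 0)
        selected[row] = cov > 0
    return np.flatnonzero(selected)


def build_windows(
    genes: list[GeneModel], up: int = 2000, down: int = 1000, *, strand_aware: bool = True
) -> list[RegulatoryWindow]:
    return [expand_window(g, up, down, strand_aware=strand_aware) for g in genes]


def snp_gene_map(
    vt: VariantTable, windows: list[RegulatoryWindow]
) -> pd.DataFrame:
    """Two-column map (locus key, comma-joined gene ids) for selected loci."""
    keys = vt.locus_keys
    d = vt.df
    records = []
    for i in select_snps(vt, windows):
        hits = [
            w.gene_id
            for w in windows
            if w.chrom == d["chrom"].iloc[i] and w.win_start <= d["pos"].iloc[i] <= w.win_end
        ]
        records.append({"locus": keys[i], "genes": ",".join(dict.fromkeys(hits))})
    return pd.DataFrame(records, columns=["locus", "genes"])
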