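"""On-disk formats and core containers.

Spot tables follow a GenePix-results-like tab-delimited layout (one file per
hybridized strain), gene annotation and gene sets are plain TSV, presence
matrices are genes x strains TSV with 1/0/NA cells, island calls are written
both as 0-based half-open BED and as a 1-based inclusive report table, and
dendrograms are written as newick with bootstrap supports on internal nodes.

All readers validate and reject malformed rows with the offending line
number rather than silently coercing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from ._utils import FormatError, round_half_up

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import Node
    from .islands import IslandCall

SPOT_COLUMNS = (
    "probe_id",
    "block",
    "row",
    "column",
    "fg_test",
    "bg_test",
    "fg_ref",
    "bg_ref",
    "flag",
)
_INT_SPOT_COLUMNS = frozenset({"block", "row", "column", "flag"})
ANNOTATION_COLUMNS = ("locus_tag", "replicon", "start", "end", "strand", "probe_id")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ArrayScan:
    """Spot-level two-channel intensities for one strain's hybridization.

    ``spots`` has one row per spot with the columns in :data:`SPOT_COLUMNS`;
    normalization adds ``corr_test``/``corr_ref`` (background-corrected
    intensities) in place. A negative ``flag`` marks a bad spot.
    """

    strain_id: str
    spots: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise FormatError(f"spot table is missing columns: {missing}")
        if self.spots["probe_id"].duplicated().any():
            dup = self.spots["probe_id"][self.spots["probe_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        for col in ("fg_test", "bg_test", "fg_ref", "bg_ref"):
            vals = self.spots[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)) or (vals < 0).any():
                raise FormatError(f"column {col} contains negative or non-finite intensities")
        for col in ("block", "row", "column"):
            if (self.spots[col].to_numpy(dtype=int) < 1).any():
                raise FormatError(f"column {col} must contain positive integers")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def good(self) -> pd.DataFrame:
        """Rows whose quality flag does not exclude them (flag >= 0)."""
        return self.spots[self.spots["flag"] >= 0]


@dataclass
class GeneTable:
    """Per-probe gene annotation plus named region/gene-set membership.

    Coordinates are 1-based inclusive. ``gene_sets`` maps a set name
    (plasmid, genomic island, metal-resistance cluster, ...) to the ordered
    locus tags it contains.
    """

    records: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"annotation is missing columns: {missing}")
        if self.records["locus_tag"].duplicated().any():
            dup = self.records["locus_tag"][self.records["locus_tag"].duplicated()].iloc[0]
            raise FormatError(f"duplicate locus_tag {dup!r}")
        bad = self.records["start"] > self.records["end"]
        if bad.any():
            tag = self.records.loc[bad, "locus_tag"].iloc[0]
            raise FormatError(f"locus {tag!r} has start > end")
        known = set(self.records["locus_tag"])
        for name, members in self.gene_sets.items():
            for m in members:
                if m not in known:
                    raise FormatError(
                        f"gene set {name!r} references unknown locus {m!r}"
                    )

    @property
    def loci(self) -> list[str]:
        return list(self.records["locus_tag"])

    def probe_to_locus(self) -> pd.Series:
        return pd.Series(
            self.records["locus_tag"].to_numpy(), index=self.records["probe_id"].to_numpy()
        )


@dataclass
class PresenceMatrix:
    """Genes x strains presence calls with the underlying fold changes.

    ``calls`` uses pandas' nullable boolean dtype: ``pd.NA`` means "no data"
    (flagged spot / tied multi-probe vote) and is deliberately distinct from
    ``False`` (absent). ``fold`` is the per-(gene, strain) fold-over-background
    ratio, NaN where there is no data; it may be None for truth-derived
    matrices that never saw intensities.
    """

    calls: pd.DataFrame
    fold: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = self.calls.astype("boolean")
        if self.fold is not None:
            if not self.fold.index.equals(self.calls.index) or not self.fold.columns.equals(
                self.calls.columns
            ):
                raise ValueError("fold and calls dimensions differ")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def strains(self) -> list[str]:
        return list(self.calls.columns)

    def present(self) -> pd.DataFrame:
        """Boolean frame: True where called present, False where absent or NA."""
        return self.calls.fillna(False).astype(bool)

    def informative(self) -> pd.DataFrame:
        return self.calls.notna()


@dataclass
class OccupancyTable:
    """Percent of each named gene set called present, per strain.

    ``values`` rows are set names, columns strains, cells one-decimal
    percentages (NaN when a set has no informative probe in a strain).
    ``detail`` is a long table with the per-cell numerator/denominator and
    the list of present member genes.
    """

    values: pd.DataFrame
    detail: pd.DataFrame


# ---------------------------------------------------------------------------
# spot tables
# ---------------------------------------------------------------------------


def write_spot_table(scan: ArrayScan, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# strain_id={scan.strain_id}\n")
        fh.write("\t".join(SPOT_COLUMNS) + "\n")
        for rec in scan.spots.itertuples(index=False):
            row = []
            for col in SPOT_COLUMNS:
                v = getattr(rec, col)
                row.append(str(int(v)) if col in _INT_SPOT_COLUMNS else str(v))
            fh.write("\t".join(row) + "\n")
    return path


def read_spot_table(path: str | Path) -> ArrayScan:
    """Parse a spot table, rejecting malformed rows with their line number."""
    path = Path(path)
    strain_id: str | None = None
    header: list[str] | None = None
    col_idx: dict[str, int] = {}
    rows: list[list] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                meta = line.lstrip("#").strip()
                if "=" in meta:
                    key, _, value = meta.partition("=")
                    if key.strip() == "strain_id":
                        strain_id = value.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in SPOT_COLUMNS if c not in header]
                if missing:
                    raise FormatError(f"{path}: missing required columns {missing}")
                col_idx = {c: header.index(c) for c in SPOT_COLUMNS}
                continue
            if len(fields) < len(header):
                raise FormatError(f"{path}: line {lineno}: expected {len(header)} fields")
            rec = []
            for col in SPOT_COLUMNS:
                tok = fields[col_idx[col]]
                if col == "probe_id":
                    rec.append(tok)
                    continue
                try:
                    rec.append(int(tok) if col in _INT_SPOT_COLUMNS else float(tok))
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric value {tok!r} in column {col}"
                    ) from None
            rows.append(rec)
    if header is None:
        raise FormatError(f"{path}: empty spot table")
    if strain_id is None:
        raise FormatError(f"{path}: no '# strain_id=...' metadata line")
    spots = pd.DataFrame(rows, columns=list(SPOT_COLUMNS))
    return ArrayScan(strain_id=strain_id, spots=spots)


# ---------------------------------------------------------------------------
# gene annotation and gene sets
# ---------------------------------------------------------------------------


def write_gene_table(table: GeneTable, annotation_path: str | Path,
                     genesets_path: str | Path | None = None) -> None:
    table.records.loc[:, list(ANNOTATION_COLUMNS)].to_csv(
        annotation_path, sep="\t", index=False
    )
    if genesets_path is not None:
        with open(genesets_path, "w", encoding="utf-8") as fh:
            fh.write("set_name\tlocus_tag\n")
            for name, members in table.gene_sets.items():
                for m in members:
                    fh.write(f"{name}\t{m}\n")


def read_gene_table(annotation_path: str | Path,
                    genesets_path: str | Path | None = None) -> GeneTable:
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"locus_tag": str, "probe_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"{annotation_path}: missing columns {missing}")
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(ann[col]):
            raise FormatError(f"{annotation_path}: column {col} must be integer")
    gene_sets: dict[str, list[str]] = {}
    if genesets_path is not None:
        gs = pd.read_csv(genesets_path, sep="\t", dtype=str)
        if list(gs.columns[:2]) != ["set_name", "locus_tag"]:
            # headerless two-column file
            gs = pd.read_csv(
                genesets_path, sep="\t", dtype=str, header=None,
                names=["set_name", "locus_tag"],
            )
        for name, grp in gs.groupby("set_name", sort=False):
            gene_sets[str(name)] = list(grp["locus_tag"])
    return GeneTable(records=ann.reset_index(drop=True), gene_sets=gene_sets)


# ---------------------------------------------------------------------------
# presence matrices
# ---------------------------------------------------------------------------


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.calls.map(lambda v: "NA" if pd.isna(v) else ("1" if v else "0"))
    out.index.name = "locus_tag"
    out.to_csv(path, sep="\t")
    return path


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus_tag", dtype=str, keep_default_na=False)
    mapping = {"1": True, "0": False, "NA": pd.NA}
    try:
        calls = df.map(lambda v: mapping[v])
    except KeyError as exc:
        raise FormatError(f"{path}: unexpected presence cell {exc.args[0]!r}") from None
    return PresenceMatrix(calls=calls.astype("boolean"))


def write_fold_matrix(matrix: PresenceMatrix, path: str | Path) -> Path:
    path = Path(path)
    if matrix.fold is None:
        raise ValueError("matrix carries no fold-change values")
    out = matrix.fold.copy()
    out.index.name = "locus_tag"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.4f")
    return path


# ---------------------------------------------------------------------------
# occupancy, islands, trees
# ---------------------------------------------------------------------------


def write_occupancy(occ: OccupancyTable, path: str | Path,
                    detail_path: str | Path | None = None) -> Path:
    path = Path(path)
    out = occ.values.map(lambda v: "NA" if pd.isna(v) else f"{v:.1f}")
    out.index.name = "region"
    out.to_csv(path, sep="\t")
    if detail_path is not None:
        occ.detail.to_csv(detail_path, sep="\t", index=False)
    return path


def write_islands_bed(islands: Iterable["IslandCall"], path: str | Path) -> Path:
    """BED (0-based half-open): replicon, start-1, end, name, score, n_genes."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#replicon\tstart\tend\tname\tscore\tn_genes\n")
        for isl in islands:
            fh.write(
                f"{isl.replicon}\t{isl.start - 1}\t{isl.end}\t{isl.name}"
                f"\t{isl.score:.3f}\t{isl.n_genes}\n"
            )
    return path


def write_islands_report(islands: Iterable["IslandCall"], path: str | Path) -> Path:
    """1-based inclusive report table: name, replicon, size (kb), coordinates."""
    path = Path(path)
    rows = []
    for isl in islands:
        rows.append(
            {
                "name": isl.name,
                "replicon": isl.replicon,
                "size_kb": f"{isl.size_kb:.1f}",
                "coordinates": f"{isl.start}-{isl.end}",
                "n_genes": isl.n_genes,
                "variability_score": f"{isl.score:.3f}",
                "group_concordance": (
                    "NA" if isl.group_concordance is None or np.isnan(isl.group_concordance)
                    else f"{isl.group_concordance:.3f}"
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "name", "replicon", "size_kb", "coordinates",
            "n_genes", "variability_score", "group_concordance",
        ],
    ).to_csv(path, sep="\t", index=False)
    return path


def newick(tree: "Node") -> str:
    """Newick string with bootstrap supports as internal node labels."""

    def render(node: "Node", parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(render(c, node.height) for c in (node.left, node.right))
            label = "" if node.support is None else f"{round_half_up(node.support, 1):g}"
            body = f"({inner}){label}"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.6g}"

    return render(tree, None) + ";"


def write_newick(tree: "Node", path: str | Path) -> Path:
    path = Path(path)
    path.write_text(newick(tree) + "\n", encoding="utf-8")
    return path


def write_truth(contents: Iterable, model, path: str | Path) -> Path:
    """Ground-truth table (strain, locus, present) for simulated strain panels."""
    path = Path(path)
    loci = list(model.loci["locus_tag"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("strain\tlocus_tag\tpresent\n")
        for content in contents:
            for tag in loci:
                fh.write(f"{content.strain_id}\t{tag}\t{int(tag in content.present)}\n")
    return path


def write_outputs(
    matrix: PresenceMatrix,
    occupancy: OccupancyTable,
    islands: list,
    dendrogram: "Node | None",
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the standard report bundle; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    manifest["presence_matrix"] = write_presence_matrix(matrix, outdir / "presence_matrix.tsv")
    if matrix.fold is not None:
        manifest["fold_matrix"] = write_fold_matrix(matrix, outdir / "fold_matrix.tsv")
    manifest["occupancy"] = write_occupancy(
        occupancy, outdir / "occupancy.tsv", outdir / "occupancy_detail.tsv"
    )
    manifest["occupancy_detail"] = outdir / "occupancy_detail.tsv"
    manifest["islands_bed"] = write_islands_bed(islands, outdir / "islands.bed")
    manifest["islands_report"] = write_islands_report(islands, outdir / "islands_report.tsv")
    if dendrogram is not None:
        manifest["tree"] = write_newick(dendrogram, outdir / "tree.nwk")
    return manifest


def write_manifest(manifest: Mapping[str, Path], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps({k: str(v) for k, v in manifest.items()}, indent=2) + "\n",
        encoding="utf-8",
    )
    return path
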