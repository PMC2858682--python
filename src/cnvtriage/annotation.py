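"""Per-CNV genomic feature annotation.

A copy-number variant (CNV) is summarised by 16 candidate attributes: its
type (gain/loss) and length, counts and densities of LINE, SINE and
segmental-duplication elements and of genes it overlaps, per-gene
evolutionary rates (dN, dS, dN/dS) and expression-stability values
averaged over overlapped genes, and two categorical flags — whether any
overlapped gene sits in a neurodegeneration pathway (KEGG hsa01510) or
has a mouse-knockout nervous-system phenotype (MGI MP:0003631).

Coordinates are 0-based half-open throughout; a 1-based inclusive input
dialect is converted on read.  Densities are elements per base pair.
Gene-derived means are missing (NaN), not zero, when no overlapped gene
contributes a value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CNV_TYPES = ("gain", "loss")
CLASS_LABELS = ("mr", "benign", "unknown")
ELEMENT_CLASSES = ("LINE", "SINE", "segdup")

#: Fixed column order of the candidate feature matrix (all 16 attributes).
CANDIDATE_FEATURES = (
    "cnv_type",
    "length_bp",
    "n_line",
    "line_density",
    "n_sine",
    "sine_density",
    "n_segdup",
    "segdup_density",
    "n_gene",
    "gene_density",
    "mean_dS",
    "mean_dN",
    "mean_dNdS",
    "kegg_flag",
    "mgi_flag",
    "mean_expr_sd",
)

#: The 13 attributes retained in the final model: the SINE count, mean dN
#: and mean dN/dS carried no accuracy and are dropped.
FINAL_FEATURES = tuple(
    f for f in CANDIDATE_FEATURES if f not in ("n_sine", "mean_dN", "mean_dNdS")
)

CATEGORICAL_FEATURES = ("cnv_type", "kegg_flag", "mgi_flag")


class CnvTableError(ValueError):
    """Raised for malformed CNV / gene tables, naming the offending line."""


@dataclass(frozen=True)
class CnvRecord:
    """A CNV interval, 0-based half-open, with optional provenance labels."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    probe_count: int | None = None
    class_label: str | None = None
    inheritance: str | None = None
    flagged: bool = False  # mosaic / complex aberration
    cnv_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV interval end ({self.end}) must exceed start ({self.start})"
            )
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}")
        if self.probe_count is not None and self.probe_count < 0:
            raise ValueError("probe_count must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval with evolutionary-rate, expression and phenotype attributes.

    ``dN``/``dS`` are per-gene substitution rates, ``expr_sd`` the standard
    deviation of log2 expression intensity across reference cell lines
    (small for dosage-stable genes).  Missing values are ``None``/NaN.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    dN: float | None = None
    dS: float | None = None
    dNdS: float | None = None
    expr_sd: float | None = None
    mgi_nervous: bool = False
    kegg_neuro: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("gene interval end must exceed start")
        for name in ("dN", "dS", "dNdS", "expr_sd"):
            v = getattr(self, name)
            if v is not None and (math.isnan(v) or v < 0):
                if math.isnan(v):
                    object.__setattr__(self, name, None)
                else:
                    raise ValueError(f"{name} must be >= 0, got {v}")


class AnnotationTrack:
    """A set of genomic intervals of one element class with overlap queries.

    Backed by one interval tree per chromosome; intervals may overlap each
    other, as repeat elements do.
    """

    def __init__(self, element_class: str, intervals: Iterable[tuple[str, int, int]]):
        self.element_class = element_class
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"track interval end must exceed start: {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            n += 1
        self._n = n

    def __len__(self) -> int:
        return self._n

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._trees)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [(iv.begin, iv.end) for iv in tree.overlap(start, end)]

    @classmethod
    def from_bed(cls, path: str | Path, element_class: str) -> "AnnotationTrack":
        """Read a headerless BED3+ file (0-based half-open)."""
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise CnvTableError(f"{path} line {lineno}: expected >=3 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise CnvTableError(f"{path} line {lineno}: non-integer coordinate") from exc
                if end <= start:
                    raise CnvTableError(f"{path} line {lineno}: end <= start")
                intervals.append((parts[0], start, end))
        return cls(element_class, intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._trees):
                for iv in sorted(self._trees[chrom]):
                    fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\n")


class GeneIndex:
    """Interval-indexed collection of :class:`GeneRecord`."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

_NA = {"", "na", "nan", "none", "."}


def _parse_optional_float(raw: str) -> float | None:
    return None if raw.strip().lower() in _NA else float(raw)


def _parse_bool(raw: str) -> bool:
    s = raw.strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise ValueError(f"cannot interpret {raw!r} as boolean")


def read_cnv_table(path: str | Path, dialect: str = "bed0") -> list[CnvRecord]:
    """Read a tab-separated CNV table into normalised records.

    The table has a header line naming at least ``chrom``, ``start``,
    ``end`` and ``type``; optional columns are ``probes``, ``class``,
    ``inheritance``, ``flag`` and ``id``.

    Parameters
    ----------
    dialect
        ``"bed0"`` — coordinates already 0-based half-open (the default);
        ``"tab1"`` — 1-based fully-inclusive, converted on read.
    """
    if dialect not in ("bed0", "tab1"):
        raise ValueError(f"dialect must be 'bed0' or 'tab1', got {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = [h.strip() for h in header_line.split("\t")]
        required = {"chrom", "start", "end", "type"}
        missing = required - set(header)
        if missing:
            raise CnvTableError(
                f"{path}: missing required column(s) {sorted(missing)} in header"
            )
        col = {name: i for i, name in enumerate(header)}
        records: list[CnvRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(required):
                raise CnvTableError(f"{path} line {lineno}: too few columns")
            try:
                start = int(parts[col["start"]])
                end = int(parts[col["end"]])
                if dialect == "tab1":
                    start -= 1  # same end: 1-based inclusive == 0-based half-open end
                probe_raw = parts[col["probes"]].strip() if "probes" in col else ""
                probe = None if probe_raw.lower() in _NA else int(probe_raw)
                cls = parts[col["class"]].strip().lower() if "class" in col else ""
                inh = parts[col["inheritance"]].strip().lower() if "inheritance" in col else ""
                flag_raw = parts[col["flag"]].strip().lower() if "flag" in col else ""
                cnv_id = parts[col["id"]].strip() if "id" in col else None
                rec = CnvRecord(
                    chrom=parts[col["chrom"]].strip(),
                    start=start,
                    end=end,
                    cnv_type=parts[col["type"]].strip().lower(),
                    probe_count=probe,
                    class_label=cls if cls not in _NA else None,
                    inheritance=inh if inh not in _NA else None,
                    flagged=flag_raw in {"mosaic", "complex"},
                    cnv_id=cnv_id,
                )
            except (ValueError, IndexError) as exc:
                raise CnvTableError(f"{path} line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def read_gene_table(path: str | Path) -> GeneIndex:
    """Read a tab-separated gene table (``NA`` marks missing values).

    Expected columns: gene_id, chrom, start, end, dN, dS, dNdS, expr_sd,
    mgi_nervous, kegg_neuro.
    """
    path = Path(path)
    genes = []
    with open(path) as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split("\t")]
        required = {"gene_id", "chrom", "start", "end"}
        missing = required - set(header)
        if missing:
            raise CnvTableError(f"{path}: missing required column(s) {sorted(missing)}")
        col = {name: i for i, name in enumerate(header)}

        def opt(parts: list[str], name: str) -> str:
            return parts[col[name]] if name in col and col[name] < len(parts) else ""

        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                genes.append(
                    GeneRecord(
                        gene_id=parts[col["gene_id"]],
                        chrom=parts[col["chrom"]],
                        start=int(parts[col["start"]]),
                        end=int(parts[col["end"]]),
                        dN=_parse_optional_float(opt(parts, "dN")),
                        dS=_parse_optional_float(opt(parts, "dS")),
                        dNdS=_parse_optional_float(opt(parts, "dNdS")),
                        expr_sd=_parse_optional_float(opt(parts, "expr_sd")),
                        mgi_nervous=_parse_bool(opt(parts, "mgi_nervous") or "false"),
                        kegg_neuro=_parse_bool(opt(parts, "kegg_neuro") or "false"),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise CnvTableError(f"{path} line {lineno}: {exc}") from exc
    return GeneIndex(genes)


def write_cnv_table(records: Sequence[CnvRecord], path: str | Path) -> None:
    cols = ["chrom", "start", "end", "type", "probes", "class", "inheritance", "flag", "id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(records):
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.cnv_type,
                        "NA" if r.probe_count is None else str(r.probe_count),
                        r.class_label or "NA",
                        r.inheritance or "NA",
                        "complex" if r.flagged else "NA",
                        r.cnv_id or f"cnv{i}",
                    ]
                )
                + "\n"
            )


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    cols = [
        "gene_id", "chrom", "start", "end",
        "dN", "dS", "dNdS", "expr_sd", "mgi_nervous", "kegg_neuro",
    ]

    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.6g}"

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id, g.chrom, str(g.start), str(g.end),
                        fmt(g.dN), fmt(g.dS), fmt(g.dNdS), fmt(g.expr_sd),
                        str(g.mgi_nervous).lower(), str(g.kegg_neuro).lower(),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def filter_cnvs(
    records: Sequence[CnvRecord],
    min_probes: int = 5,
    min_length_bp: int = 10_000,
    drop_flagged_complex: bool = True,
) -> tuple[list[CnvRecord], dict[str, int]]:
    """Apply array-QC filters: drop CNVs supported by fewer than
    ``min_probes`` targets, shorter than ``min_length_bp``, or flagged as
    mosaic/complex aberrations.

    Records without a probe count (e.g. literature CNVs) pass the probe
    rule; only an explicit count below the threshold excludes.  Returns
    the retained records and per-rule exclusion counts (a record failing
    several rules increments each).
    """
    retained: list[CnvRecord] = []
    excluded = {"probes": 0, "length": 0, "flagged": 0}
    for r in records:
        ok = True
        if r.probe_count is not None and r.probe_count < min_probes:
            excluded["probes"] += 1
            ok = False
        if r.length < min_length_bp:
            excluded["length"] += 1
            ok = False
        if drop_flagged_complex and r.flagged:
            excluded["flagged"] += 1
            ok = False
        if ok:
            retained.append(r)
    return retained, excluded


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def count_overlaps(cnv: CnvRecord, track: AnnotationTrack, containment: bool = False) -> int:
    """Number of track intervals sharing >=1 bp with the CNV.

    With ``containment=True`` only intervals fully inside the CNV count.
    A CNV on a chromosome absent from the track yields 0 with a logged
    warning (likely a build mismatch).
    """
    if cnv.chrom not in track._trees:
        logger.warning(
            "chromosome %r not present in %s track; overlap count is 0",
            cnv.chrom, track.element_class,
        )
        return 0
    hits = track.overlapping(cnv.chrom, cnv.start, cnv.end)
    if containment:
        return sum(1 for s, e in hits if s >= cnv.start and e <= cnv.end)
    return len(hits)


def element_density(count: int, length_bp: int) -> float:
    """Elements per base pair: ``count / length_bp``."""
    if length_bp < 1:
        raise ValueError(f"length_bp must be >= 1, got {length_bp}")
    return count / length_bp


def _mean_or_none(values: list[float]) -> float | None:
    return sum(values) / len(values) if values else None


def gene_attributes(cnv: CnvRecord, genes: GeneIndex) -> dict[str, object]:
    """Gene-derived attributes of one CNV.

    Means run over overlapping genes that carry the attribute; with no
    contributing gene the mean is missing, never 0 — a gene-free CNV is
    uninformative about evolutionary rates, not evidence of rate 0.
    Flags are ORs over overlapping genes.
    """
    hits = genes.overlapping(cnv.chrom, cnv.start, cnv.end)
    out: dict[str, object] = {
        "n_gene": len(hits),
        "gene_density": element_density(len(hits), cnv.length),
        "mean_dS": _mean_or_none([g.dS for g in hits if g.dS is not None]),
        "mean_dN": _mean_or_none([g.dN for g in hits if g.dN is not None]),
        "mean_dNdS": _mean_or_none([g.dNdS for g in hits if g.dNdS is not None]),
        "mean_expr_sd": _mean_or_none([g.expr_sd for g in hits if g.expr_sd is not None]),
        "mgi_flag": any(g.mgi_nervous for g in hits),
        "kegg_flag": any(g.kegg_neuro for g in hits),
    }
    return out


def annotate_cnv(
    cnv: CnvRecord,
    tracks: Mapping[str, AnnotationTrack],
    genes: GeneIndex,
    containment: bool = False,
) -> dict[str, object]:
    """Compute the full 16-attribute candidate feature vector of one CNV.

    ``tracks`` must supply the keys ``LINE``, ``SINE`` and ``segdup``.
    """
    for key in ELEMENT_CLASSES:
        if key not in tracks:
            raise KeyError(f"missing annotation track {key!r}")
    n_line = count_overlaps(cnv, tracks["LINE"], containment)
    n_sine = count_overlaps(cnv, tracks["SINE"], containment)
    n_segdup = count_overlaps(cnv, tracks["segdup"], containment)
    vec: dict[str, object] = {
        "cnv_type": cnv.cnv_type,
        "length_bp": cnv.length,
        "n_line": n_line,
        "line_density": element_density(n_line, cnv.length),
        "n_sine": n_sine,
        "sine_density": element_density(n_sine, cnv.length),
        "n_segdup": n_segdup,
        "segdup_density": element_density(n_segdup, cnv.length),
    }
    vec.update(gene_attributes(cnv, genes))
    return {k: vec[k] for k in CANDIDATE_FEATURES}


def build_feature_matrix(
    cnvs: Sequence[CnvRecord],
    tracks: Mapping[str, AnnotationTrack],
    genes: GeneIndex,
    containment: bool = False,
) -> pd.DataFrame:
    """Annotate a CNV list into a feature matrix (one row per CNV, columns
    in :data:`CANDIDATE_FEATURES` order; missing means are NaN).

    The index holds CNV ids; a ``class_label`` column is appended when any
    record carries one.
    """
    rows = [annotate_cnv(c, tracks, genes, containment) for c in cnvs]
    idx = [c.cnv_id or f"cnv{i}" for i, c in enumerate(cnvs)]
    df = pd.DataFrame(rows, index=pd.Index(idx, name="id"), columns=list(CANDIDATE_FEATURES))
    for col in ("mean_dS", "mean_dN", "mean_dNdS", "mean_expr_sd"):
        df[col] = df[col].astype(float)
    if any(c.class_label for c in cnvs):
        df["class_label"] = [c.class_label or "unknown" for c in cnvs]
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="id", na_rep="NA")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    for col in ("kegg_flag", "mgi_flag"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Collinearity pruning
# ---------------------------------------------------------------------------

_VIF_CAP = 1e12  # reported in place of an infinite VIF from exact collinearity


def _vif_single(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from OLS of column j on the others (with
    intercept)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return _VIF_CAP  # constant column: collinear with the intercept
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    if r2 >= 1.0 - 1e-12:
        return _VIF_CAP
    return 1.0 / (1.0 - r2)


def vif_prune(
    features: pd.DataFrame,
    vif_threshold: float = 10.0,
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the most collinear continuous feature until every
    variance inflation factor is at or below ``vif_threshold``.

    VIF_j = 1/(1-R²_j) with R²_j from regressing feature j on the
    remaining features.  Exactly collinear features have infinite VIF; the
    tie-break removes the member latest in column order.  Returns the
    retained feature names and a table with each feature's final VIF (or
    the VIF at removal) and removal order (0 = kept).

    Rows containing NaN are dropped before the regressions.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    clean = features.dropna(axis=0)
    if clean.shape[0] < features.shape[1] + 1:
        raise ValueError("need more complete rows than features")
    cols = list(features.columns)
    X = clean.to_numpy(dtype=float)
    active = list(range(len(cols)))
    removal_order: dict[str, int] = {c: 0 for c in cols}
    final_vif: dict[str, float] = {}
    step = 0
    while len(active) >= 2:
        vifs = np.array([_vif_single(X[:, active], k) for k in range(len(active))])
        worst = int(np.max(np.flatnonzero(vifs == vifs.max())))  # later column wins ties
        if vifs[worst] <= vif_threshold:
            for k, col_idx in enumerate(active):
                final_vif[cols[col_idx]] = float(vifs[k])
            break
        step += 1
        removed = active.pop(worst)
        removal_order[cols[removed]] = step
        final_vif[cols[removed]] = float(vifs[worst])
    else:
        final_vif[cols[active[0]]] = 1.0
    retained = [cols[i] for i in active]
    table = pd.DataFrame(
        {
            "vif": [final_vif.get(c, np.nan) for c in cols],
            "removal_order": [removal_order[c] for c in cols],
            "retained": [c in retained for c in cols],
        },
        index=pd.Index(cols, name="feature"),
    )
    return retained, table
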