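"""Readers and writers for the pipeline's tabular formats.

Supported formats
-----------------
* counts TSV — first column probe id, second column probe class
  (``Endogenous``/``Positive``/``Negative``), one column per assay, integer cells;
* RCC-like lane directories — the section-structured per-lane CSV dialect
  (``<Header>`` … ``<Code_Summary>``), one file per assay, joined by probe id;
* sample metadata TSV — columns ``assay_id``, ``sample_id``, ``group``, ``batch``;
* GMT gene-set collections, with an optional ``gene|+1`` / ``gene|-1`` suffix
  carrying the expected direction of each member;
* generic result tables (TSV, floats rendered to 6 significant digits).

All readers validate on construction and never silently reorder probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_CLASSES = ("Endogenous", "Positive", "Negative")
GROUPS = ("control", "CR", "PR", "NR")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountMatrix:
    """Raw probe-by-assay counts with per-probe class annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes x assays, non-negative; index holds probe ids.
    probe_class : pandas.Series
        One of ``Endogenous``/``Positive``/``Negative`` per probe, indexed
        like ``values``.
    """

    values: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate assay id: {dup!r}")
        if not self.probe_class.index.equals(v.index):
            raise ValidationError("probe_class index does not match count rows")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValidationError(f"unknown probe class(es): {sorted(bad)}")
        for cls in PROBE_CLASSES:
            if not (self.probe_class == cls).any():
                raise ValidationError(f"no probe of class {cls!r} present")
        arr = v.to_numpy()
        if np.isnan(arr.astype(float)).any():
            probe = v.index[np.isnan(arr.astype(float)).any(axis=1)][0]
            raise ValidationError(f"missing count for probe {probe!r}")
        if (arr < 0).any():
            probe = v.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative count for probe {probe!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    def of_class(self, cls: str) -> pd.DataFrame:
        """Counts restricted to one probe class, original order preserved."""
        return self.values.loc[self.probe_class == cls]

    @property
    def endogenous(self) -> pd.DataFrame:
        return self.of_class("Endogenous")

    @property
    def positive(self) -> pd.DataFrame:
        return self.of_class("Positive")

    @property
    def negative(self) -> pd.DataFrame:
        return self.of_class("Negative")


@dataclass
class SampleTable:
    """Assay-level metadata: which sample, response group and assay batch.

    Control samples re-assayed in a second batch appear as two rows sharing a
    ``sample_id`` but with distinct ``assay_id``\\ s.
    """

    frame: pd.DataFrame

    REQUIRED = ("assay_id", "sample_id", "group", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"metadata missing column(s): {missing}")
        f = self.frame
        if f["assay_id"].duplicated().any():
            dup = f.loc[f["assay_id"].duplicated(), "assay_id"].iloc[0]
            raise ValidationError(f"duplicate assay id in metadata: {dup!r}")
        bad = set(f["group"].unique()) - set(GROUPS)
        if bad:
            raise ValidationError(
                f"group labels outside {GROUPS}: {sorted(bad)}"
            )
        self.frame = f.reset_index(drop=True)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.frame["assay_id"])

    @property
    def batches(self) -> list[str]:
        return sorted(self.frame["batch"].astype(str).unique())

    def group_of(self) -> pd.Series:
        return self.frame.set_index("assay_id")["group"]

    def batch_of(self) -> pd.Series:
        return self.frame.set_index("assay_id")["batch"].astype(str)

    def anchors(self) -> list[str]:
        """Sample ids assayed in more than one batch (batch anchors)."""
        per = self.frame.groupby("sample_id")["batch"].nunique()
        return sorted(per.index[per > 1])

    def check_matches(self, counts: CountMatrix) -> None:
        meta_ids = set(self.frame["assay_id"])
        count_ids = set(counts.assay_ids)
        if meta_ids != count_ids:
            raise ValidationError(
                "assay ids differ between counts and metadata: "
                f"only-in-counts={sorted(count_ids - meta_ids)[:5]}, "
                f"only-in-meta={sorted(meta_ids - count_ids)[:5]}"
            )


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: list[str]
    directions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")
        if self.directions is not None:
            missing = set(self.members) - set(self.directions)
            if missing:
                raise ValidationError(
                    f"gene set {self.set_id!r}: directions missing for "
                    f"{sorted(missing)[:5]}"
                )


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from a TSV file or a directory of RCC-like lanes."""
    if format == "tsv":
        return _read_counts_tsv(Path(path))
    if format == "rcc_dir":
        return _read_rcc_dir(Path(path))
    raise ValueError(f"unknown counts format: {format!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: counts TSV needs probe id, probe class and >=1 assay column"
        )
    probe_col, class_col = df.columns[0], df.columns[1]
    df = df.set_index(probe_col)
    df.index.name = None
    probe_class = df[class_col].astype(str)
    probe_class.name = "probe_class"
    values = df.drop(columns=[class_col])
    return CountMatrix(values=values, probe_class=probe_class)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    out = counts.values.copy()
    out.insert(0, "probe_class", counts.probe_class)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


_RCC_KNOWN_SECTIONS = {
    "header", "sample_attributes", "lane_attributes", "code_summary", "messages",
}


def _parse_rcc_file(path: Path) -> tuple[str, pd.DataFrame]:
    """Parse one RCC-like lane file into (assay id, code summary frame)."""
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1].lower()
            if current not in _RCC_KNOWN_SECTIONS:
                logger.warning("%s:%d: ignoring unknown RCC section <%s>",
                               path.name, lineno, current)
            sections.setdefault(current, [])
        elif current is not None:
            sections[current].append(line)
    if "code_summary" not in sections or not sections["code_summary"]:
        raise ValidationError(f"{path}: no Code_Summary section")

    assay_id = path.stem
    for line in sections.get("sample_attributes", []):
        key, _, value = line.partition(",")
        if key.strip().lower() == "id" and value.strip():
            assay_id = value.strip()

    rows = [line.split(",") for line in sections["code_summary"]]
    header = [h.strip() for h in rows[0]]
    body = pd.DataFrame(rows[1:], columns=header)
    for col in ("CodeClass", "Name", "Count"):
        if col not in body.columns:
            raise ValidationError(f"{path}: Code_Summary lacks column {col!r}")
    body["Count"] = pd.to_numeric(body["Count"])
    return assay_id, body


def _read_rcc_dir(path: Path) -> CountMatrix:
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in {".rcc", ".csv", ".txt"})
    if not files:
        raise ValidationError(f"{path}: no RCC-like lane files found")
    columns: dict[str, pd.Series] = {}
    probe_class: pd.Series | None = None
    for f in files:
        assay_id, body = _parse_rcc_file(f)
        cls = body.set_index("Name")["CodeClass"].astype(str)
        counts = body.set_index("Name")["Count"]
        if probe_class is None:
            probe_class = cls
        elif not probe_class.index.equals(cls.index):
            raise ValidationError(
                f"{f}: Code_Summary probes differ from first lane"
            )
        if assay_id in columns:
            raise ValidationError(f"duplicate assay id across lanes: {assay_id!r}")
        columns[assay_id] = counts
    values = pd.DataFrame(columns)
    assert probe_class is not None
    probe_class.name = "probe_class"
    probe_class.index.name = None
    values.index.name = None
    return CountMatrix(values=values, probe_class=probe_class)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_meta(path: str | Path) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(frame=frame)


def write_meta(meta: SampleTable, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; ``gene|+1`` / ``gene|-1`` member suffixes become directions."""
    coll = GeneSetCollection()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >=3"
            )
        set_id, description, raw_members = fields[0], fields[1], fields[2:]
        members: list[str] = []
        directions: dict[str, int] = {}
        any_dir = False
        for m in raw_members:
            if not m:
                continue
            gene, _, suffix = m.partition("|")
            members.append(gene)
            if suffix:
                if suffix not in ("+1", "-1"):
                    raise ValidationError(
                        f"{path}:{lineno}: bad direction suffix {suffix!r}"
                    )
                directions[gene] = int(suffix)
                any_dir = True
        if set_id in coll.sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        coll.sets[set_id] = GeneSet(
            set_id=set_id,
            description=description,
            members=members,
            directions=directions if any_dir else None,
        )
    return coll


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV; floats use 6 significant digits."""
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
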