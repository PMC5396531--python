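"""Parcellations, connectivity matrices and cohort tables.

The pipeline consumes weighted, undirected, per-subject-per-visit
connectivity matrices over a labelled parcellation (cortical regions plus,
optionally, striatal seed regions), together with a cohort table carrying
group membership and baseline covariates.  This module defines the in-memory
containers and the plain-text readers/writers for those inputs.

File dialects
-------------
Region table
    TSV with header columns ``name``, ``hemisphere`` (``L``/``R``) and
    ``tissue_class`` (``cortical``/``striatal``).  Region ids are assigned
    in file order, 0-based.
Connectome, dense dialect
    ``n x n`` CSV whose header row carries the region names in atlas order.
Connectome, edge-list dialect
    3-column TSV ``i, j, weight`` over region indices with ``i < j``
    (undirected half-matrix); unlisted pairs are zero.
Cohort table
    CSV with one row per subject.

Missing visits are represented by absence of the observation, never by a
zero-filled matrix: zeros are meaningful connection weights.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEMISPHERES = ("L", "R")
TISSUE_CLASSES = ("cortical", "striatal")
GROUPS = ("control", "preHD")

#: tolerance for the dense-dialect symmetry check
SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    hemisphere: str  # "L" or "R"
    tissue_class: str  # "cortical" or "striatal"


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered parcellation with hemisphere and cortical/striatal labels."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if ids != list(range(len(ids))):
            raise FormatError("region_ids must be contiguous 0..n-1 in order")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate region names: {dup}")
        for r in self.regions:
            if r.hemisphere not in HEMISPHERES:
                raise FormatError(f"region {r.name!r}: unknown hemisphere {r.hemisphere!r}")
            if r.tissue_class not in TISSUE_CLASSES:
                raise FormatError(f"region {r.name!r}: unknown tissue_class {r.tissue_class!r}")
        for h in HEMISPHERES:
            if not any(r.hemisphere == h and r.tissue_class == "cortical" for r in self.regions):
                raise FormatError(f"atlas needs at least one cortical region in hemisphere {h}")

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def cortical_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions if r.tissue_class == "cortical"], dtype=int)

    @property
    def striatal_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions if r.tissue_class == "striatal"], dtype=int)

    def hemisphere_of(self, region_id: int) -> str:
        return self.regions[region_id].hemisphere

    def is_cortical(self, region_id: int) -> bool:
        return self.regions[region_id].tissue_class == "cortical"


@dataclass
class ConnectomeObservation:
    """One subject-visit weighted symmetric connectivity matrix.

    ``time`` is years since baseline, ``t = visit - 1`` under the study's
    annual-visit schedule.
    """

    subject_id: str
    visit: int
    W: np.ndarray
    time: float | None = None

    def __post_init__(self) -> None:
        if self.visit < 1:
            raise FormatError(f"visit must be >= 1, got {self.visit}")
        if self.time is None:
            self.time = float(self.visit - 1)
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise FormatError(f"connectivity matrix must be square, got shape {W.shape}")
        if not np.allclose(W, W.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise FormatError("connectivity matrix is asymmetric beyond tolerance")
        if (W < 0).any():
            raise FormatError("negative connection weights are not allowed")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise FormatError("diagonal must be exactly zero")
        # symmetrize away round-trip noise below the tolerance
        self.W = (W + W.T) / 2.0


@dataclass(frozen=True)
class CohortRecord:
    """Per-subject demographic and clinical record (constant across visits)."""

    subject_id: str
    group: str  # "control" or "preHD"
    age: float
    sex: str  # "M" or "F"
    site: str
    education: float
    cag: int | None = None  # CAG repeat length, preHD only
    cognition: float | None = None  # baseline global cognitive composite

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"subject {self.subject_id!r}: unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise FormatError(f"subject {self.subject_id!r}: unknown sex {self.sex!r}")


@dataclass
class LongDataset:
    """Atlas + longitudinal observations + cohort table, cross-validated."""

    atlas: RegionAtlas
    observations: list[ConnectomeObservation]
    cohort: list[CohortRecord]

    def __post_init__(self) -> None:
        known = {c.subject_id for c in self.cohort}
        if len(known) != len(self.cohort):
            raise FormatError("duplicate subject in cohort table")
        seen: dict[str, list[int]] = {}
        for obs in self.observations:
            if obs.subject_id not in known:
                raise FormatError(f"observation for unknown subject {obs.subject_id!r}")
            if obs.W.shape[0] != self.atlas.n:
                raise FormatError(
                    f"observation {obs.subject_id!r} visit {obs.visit}: "
                    f"matrix size {obs.W.shape[0]} != atlas size {self.atlas.n}"
                )
            seen.setdefault(obs.subject_id, []).append(obs.visit)
        for sid, visits in seen.items():
            if sorted(visits) != visits or len(set(visits)) != len(visits):
                raise FormatError(f"subject {sid!r}: visits must be strictly increasing")

    @property
    def records_by_subject(self) -> dict[str, CohortRecord]:
        return {c.subject_id: c for c in self.cohort}

    def subjects(self, group: str | None = None) -> list[str]:
        return [c.subject_id for c in self.cohort if group is None or c.group == group]

    def observations_of(self, subject_id: str) -> list[ConnectomeObservation]:
        return [o for o in self.observations if o.subject_id == subject_id]


# ---------------------------------------------------------------------------
# readers / writers


def read_region_table(path: str | Path) -> RegionAtlas:
    """Read a parcellation TSV (columns name, hemisphere, tissue_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "hemisphere", "tissue_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    regions = []
    for idx, row in df.iterrows():
        h, tc = row["hemisphere"], row["tissue_class"]
        if h not in HEMISPHERES:
            raise FormatError(f"{path} row {idx}: unknown hemisphere {h!r}")
        if tc not in TISSUE_CLASSES:
            raise FormatError(f"{path} row {idx}: unknown tissue_class {tc!r}")
        regions.append(Region(int(idx), row["name"], h, tc))
    atlas = RegionAtlas(tuple(regions))
    logger.info("read %d regions from %s", atlas.n, path)
    return atlas


def write_region_table(atlas: RegionAtlas, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [r.name for r in atlas.regions],
            "hemisphere": [r.hemisphere for r in atlas.regions],
            "tissue_class": [r.tissue_class for r in atlas.regions],
        }
    ).to_csv(path, sep="\t", index=False)


_FNAME_RE = re.compile(r"sub-(?P<subject>[A-Za-z0-9]+)_visit-(?P<visit>\d+)")


def read_connectome(
    path: str | Path,
    atlas: RegionAtlas,
    subject_id: str | None = None,
    visit: int | None = None,
) -> ConnectomeObservation:
    """Read one connectivity matrix (dense CSV or 3-column edge-list TSV).

    Subject and visit may be passed explicitly or encoded in the file name as
    ``sub-<id>_visit-<v>``.
    """
    path = Path(path)
    if subject_id is None or visit is None:
        m = _FNAME_RE.search(path.name)
        if m is None:
            raise FormatError(
                f"{path}: subject_id/visit not given and file name does not match 'sub-<id>_visit-<v>'"
            )
        subject_id = subject_id or m.group("subject")
        visit = visit or int(m.group("visit"))

    if path.suffix.lower() == ".tsv":
        W = _read_edge_list(path, atlas.n)
    else:
        W = _read_dense(path, atlas)
    return ConnectomeObservation(subject_id=subject_id, visit=visit, W=W)


def _read_dense(path: Path, atlas: RegionAtlas) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != atlas.names:
        raise FormatError(f"{path}: header region names do not match atlas order")
    W = df.to_numpy(dtype=float)
    if W.shape != (atlas.n, atlas.n):
        raise FormatError(f"{path}: expected {atlas.n}x{atlas.n} matrix, got {W.shape}")
    if not np.allclose(W, W.T, atol=SYMMETRY_TOL, rtol=0.0):
        raise FormatError(f"{path}: dense matrix asymmetric beyond {SYMMETRY_TOL}")
    return W


def _read_edge_list(path: Path, n: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "weight"], comment="#")
    W = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for row_no, (i, j, w) in enumerate(df.itertuples(index=False)):
        i, j, w = int(i), int(j), float(w)
        if not (0 <= i < n and 0 <= j < n):
            raise FormatError(f"{path} row {row_no}: index out of range for n={n}")
        if i >= j:
            raise FormatError(f"{path} row {row_no}: edge-list dialect requires i < j")
        if (i, j) in seen:
            raise FormatError(f"{path} row {row_no}: duplicate edge ({i}, {j})")
        if w < 0:
            raise FormatError(f"{path} row {row_no}: negative weight {w}")
        seen.add((i, j))
        W[i, j] = W[j, i] = w
    logger.info("read %d edges from %s", len(seen), path)
    return W


def write_connectome(obs: ConnectomeObservation, path: str | Path, atlas: RegionAtlas) -> None:
    """Write the dense dialect with a bit-exact float round trip."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(atlas.names) + "\n")
        for row in obs.W:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV; empty CAG/cognition cells are treated as absent."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "site", "education"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cag = row.get("cag")
        cog = row.get("cognition")
        records.append(
            CohortRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                site=str(row["site"]),
                education=float(row["education"]),
                cag=None if cag is None or pd.isna(cag) else int(cag),
                cognition=None if cog is None or pd.isna(cog) else float(cog),
            )
        )
    logger.info("read %d cohort records from %s", len(records), path)
    return records


def write_cohort_table(cohort: Sequence[CohortRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": c.subject_id,
                "group": c.group,
                "age": c.age,
                "sex": c.sex,
                "site": c.site,
                "education": c.education,
                "cag": c.cag,
                "cognition": c.cognition,
            }
            for c in cohort
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# group-level helpers


def average_connectomes(
    dataset: LongDataset,
    subject_filter: Callable[[CohortRecord], bool] | None = None,
    visit_filter: Callable[[int], bool] | None = None,
) -> np.ndarray:
    """Elementwise mean of the selected observations' connectivity matrices."""
    records = dataset.records_by_subject
    selected = [
        obs.W
        for obs in dataset.observations
        if (subject_filter is None or subject_filter(records[obs.subject_id]))
        and (visit_filter is None or visit_filter(obs.visit))
    ]
    if not selected:
        raise ValueError("no observations match the given filters")
    return np.mean(selected, axis=0)


def build_long_table(
    dataset: LongDataset,
    strengths: Mapping[tuple[str, int], float],
) -> pd.DataFrame:
    """Long-format modelling table: one row per supplied (subject, visit).

    Columns: subject, visit, time, group, age, sex, site, education, cag,
    cognition, value.  ``time = visit - 1`` (years on study, baseline 0).
    """
    records = dataset.records_by_subject
    rows = []
    for (sid, visit), value in strengths.items():
        if sid not in records:
            raise FormatError(f"strength supplied for unknown subject {sid!r}")
        rec = records[sid]
        rows.append(
            {
                "subject": sid,
                "visit": visit,
                "time": float(visit - 1),
                "group": rec.group,
                "age": rec.age,
                "sex": rec.sex,
                "site": rec.site,
                "education": rec.education,
                "cag": rec.cag,
                "cognition": rec.cognition,
                "value": float(value),
            }
        )
    return pd.DataFrame(rows)
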