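"""Cohort rosters, parcellation tables, and parcellated time-course I/O.

All on-disk formats are plain tab-separated text:

* roster TSV: one row per scan with columns ``subject_id``, ``family_id``,
  ``scan_id``, ``session`` (calendar date or small ordinal);
* zygosity TSV: ``subject_a``, ``subject_b``, ``zygosity`` with zygosity in
  ``{MZ, DZ, sibling}``;
* parcellation TSV: ``roi_id``, ``network``, ``n_vertices``, ``hemisphere``;
* time courses: one TSV per scan, frames in rows, ROIs in columns, optional
  header row of roi ids;
* frame-displacement traces: one value per frame, plain text.

Imaging-format ingestion (NIfTI/CIFTI) is out of scope; users convert to the
frames-by-ROIs text layout first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZYGOSITY_CLASSES = ("MZ", "DZ", "sibling")

#: Functional-network vocabulary (Gordon-style cortical communities plus a
#: subcortical network and the explicit "unassigned" bucket).
KNOWN_NETWORKS = (
    "auditory",
    "cingulo_opercular",
    "cingulo_parietal",
    "default",
    "dorsal_attention",
    "fronto_parietal",
    "retrosplenial_temporal",
    "salience",
    "somatosensory_hand",
    "somatosensory_mouth",
    "ventral_attention",
    "visual",
    "subcortical",
    "unassigned",
)

_ZYGOSITY_ALIASES = {
    "mz": "MZ",
    "monozygotic": "MZ",
    "identical": "MZ",
    "dz": "DZ",
    "dizygotic": "DZ",
    "fraternal": "DZ",
    "sib": "sibling",
    "sibling": "sibling",
    "nontwin": "sibling",
}


class CohortError(ValueError):
    """Raised on roster/parcellation inconsistencies."""


@dataclass
class ScanTimeSeries:
    """One scan's frames-by-ROIs signal matrix.

    Attributes
    ----------
    data : ndarray of shape (frames, M)
    tr : float
        Sampling interval in seconds.
    frame_mask : bool ndarray of length frames
        True for retained frames.  Downstream consumers operate on
        ``retained()`` only.
    scan_id : str
    """

    data: np.ndarray
    tr: float
    frame_mask: np.ndarray = None
    scan_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise CohortError("time-series data must be 2-D (frames x ROIs)")
        if self.tr <= 0:
            raise CohortError(f"tr must be positive, got {self.tr}")
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
            if self.frame_mask.shape != (self.data.shape[0],):
                raise CohortError("frame_mask length must equal frame count")
        if not np.isfinite(self.data[self.frame_mask]).all():
            bad = np.argwhere(~np.isfinite(self.data))
            r, c = bad[0]
            raise CohortError(
                f"non-finite value among retained frames at frame {r}, ROI column {c}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def retained(self) -> np.ndarray:
        """Data restricted to retained frames."""
        return self.data[self.frame_mask]

    def with_data(self, data: np.ndarray, frame_mask=None) -> "ScanTimeSeries":
        return ScanTimeSeries(
            data=data,
            tr=self.tr,
            frame_mask=self.frame_mask.copy() if frame_mask is None else frame_mask,
            scan_id=self.scan_id,
        )


@dataclass
class ParcellationTable:
    """ROI-to-network mapping with ROI sizes."""

    table: pd.DataFrame  # columns roi_id, network, n_vertices, hemisphere

    def __post_init__(self):
        t = self.table
        required = {"roi_id", "network"}
        missing = required - set(t.columns)
        if missing:
            raise CohortError(f"parcellation table missing columns {sorted(missing)}")
        ids = t["roi_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise CohortError("duplicate roi_id in parcellation table")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise CohortError("non-contiguous ids: roi_id must be 1..M without gaps")
        unknown = set(t["network"]) - set(KNOWN_NETWORKS)
        if unknown:
            warnings.warn(
                f"unknown network labels {sorted(unknown)} mapped to 'unassigned'"
            )
            logger.warning("unknown network labels %s -> unassigned", sorted(unknown))
            self.table = t = t.assign(
                network=t["network"].where(t["network"].isin(KNOWN_NETWORKS), "unassigned")
            )
        self.table = t.sort_values("roi_id").reset_index(drop=True)

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Assigned networks present in the table (excludes 'unassigned')."""
        return sorted(set(self.table["network"]) - {"unassigned"})

    def network_members(self, network: str) -> np.ndarray:
        """0-based column indices of ROIs in `network`."""
        return np.flatnonzero((self.table["network"] == network).to_numpy())

    def count(self, network: str) -> int:
        return int((self.table["network"] == network).sum())


@dataclass
class Cohort:
    """Subjects, families, zygosity pairs, and scan sessions.

    Zygosity is stored pairwise because the analysis unit is the pair.
    ``session`` may be a calendar date or a small ordinal; inter-session
    intervals use whichever was provided.
    """

    subjects: pd.DataFrame  # subject_id, family_id
    scans: pd.DataFrame  # scan_id, subject_id, session
    zygosity_pairs: pd.DataFrame = None  # subject_a, subject_b, zygosity
    anatomy: pd.DataFrame = None  # subject_id, roi_id, <measures...>, head_size

    def __post_init__(self):
        if self.subjects is None or len(self.subjects) == 0:
            raise CohortError("empty cohort")
        if self.zygosity_pairs is None:
            self.zygosity_pairs = pd.DataFrame(
                columns=["subject_a", "subject_b", "zygosity"]
            )
        self.validate()

    def validate(self) -> None:
        subs = self.subjects
        if subs["subject_id"].duplicated().any():
            dup = subs.loc[subs["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortError(f"duplicate subject_id {dup!r}")
        if self.scans["scan_id"].duplicated().any():
            dup = self.scans.loc[self.scans["scan_id"].duplicated(), "scan_id"].iloc[0]
            raise CohortError(f"duplicate scan_id {dup!r}")
        known = set(subs["subject_id"])
        orphan = set(self.scans["subject_id"]) - known
        if orphan:
            raise CohortError(f"scans reference unknown subjects {sorted(orphan)}")
        scanless = known - set(self.scans["subject_id"])
        if scanless:
            raise CohortError(f"subjects without any scan: {sorted(scanless)}")
        fam = dict(zip(subs["subject_id"], subs["family_id"]))
        for _, row in self.zygosity_pairs.iterrows():
            a, b = row["subject_a"], row["subject_b"]
            for s in (a, b):
                if s not in fam:
                    raise CohortError(f"zygosity pair references unknown subject {s!r}")
            if fam[a] != fam[b]:
                raise CohortError(
                    f"zygosity pair ({a!r}, {b!r}) spans families "
                    f"{fam[a]!r} and {fam[b]!r}"
                )
            if row["zygosity"] not in ZYGOSITY_CLASSES:
                raise CohortError(f"unknown zygosity class {row['zygosity']!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def family_of(self, subject_id) -> str:
        m = dict(zip(self.subjects["subject_id"], self.subjects["family_id"]))
        return m[subject_id]

    def subject_of_scan(self, scan_id) -> str:
        m = dict(zip(self.scans["scan_id"], self.scans["subject_id"]))
        return m[scan_id]

    def zygosity_of(self, subject_a, subject_b) -> str | None:
        """Zygosity class of an (unordered) subject pair, or None."""
        key = frozenset((subject_a, subject_b))
        for _, row in self.zygosity_pairs.iterrows():
            if frozenset((row["subject_a"], row["subject_b"])) == key:
                return row["zygosity"]
        return None

    def families_with_twins(self) -> set:
        twins = self.zygosity_pairs[self.zygosity_pairs["zygosity"].isin(["MZ", "DZ"])]
        fam = dict(zip(self.subjects["subject_id"], self.subjects["family_id"]))
        return {fam[s] for s in twins["subject_a"]} | {fam[s] for s in twins["subject_b"]}


def normalize_zygosity(label: str) -> str:
    try:
        return _ZYGOSITY_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise CohortError(f"unknown zygosity label {label!r}") from None


def load_cohort(roster_path, zygosity_path=None, anatomy_path=None) -> Cohort:
    """Read a roster TSV (and optional zygosity / anatomy TSVs) into a Cohort.

    The roster has one row per scan: subject_id, family_id, scan_id, session.
    """
    roster = pd.read_csv(roster_path, sep="\t", dtype=str)
    required = {"subject_id", "family_id", "scan_id"}
    missing = required - set(roster.columns)
    if missing:
        raise CohortError(f"roster missing columns {sorted(missing)}")
    if "session" not in roster.columns:
        roster["session"] = "1"
    subjects = (
        roster[["subject_id", "family_id"]].drop_duplicates("subject_id").reset_index(drop=True)
    )
    conflicting = roster.groupby("subject_id")["family_id"].nunique()
    if (conflicting > 1).any():
        bad = conflicting[conflicting > 1].index.tolist()
        raise CohortError(f"subjects with conflicting family_id: {bad}")
    scans = roster[["scan_id", "subject_id", "session"]].copy()
    zyg = None
    if zygosity_path is not None:
        zyg = pd.read_csv(zygosity_path, sep="\t", dtype=str)
        zyg["zygosity"] = zyg["zygosity"].map(normalize_zygosity)
    anatomy = None
    if anatomy_path is not None:
        anatomy = pd.read_csv(anatomy_path, sep="\t")
    return Cohort(subjects=subjects, scans=scans, zygosity_pairs=zyg, anatomy=anatomy)


def save_cohort(cohort: Cohort, roster_path, zygosity_path=None) -> None:
    roster = cohort.scans.merge(cohort.subjects, on="subject_id")
    roster = roster[["subject_id", "family_id", "scan_id", "session"]]
    roster.to_csv(roster_path, sep="\t", index=False)
    if zygosity_path is not None:
        cohort.zygosity_pairs.to_csv(zygosity_path, sep="\t", index=False)


def load_parcellation(path) -> ParcellationTable:
    table = pd.read_csv(path, sep="\t")
    return ParcellationTable(table=table)


def save_parcellation(parcellation: ParcellationTable, path) -> None:
    parcellation.table.to_csv(path, sep="\t", index=False)


def load_timeseries(path, parcellation: ParcellationTable, tr: float = 2.5,
                    scan_id: str | None = None) -> ScanTimeSeries:
    """Read a frames-by-ROIs TSV and validate it against the parcellation."""
    path = Path(path)
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = not np.issubdtype(first.dtypes.iloc[0], np.number)
    raw = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    data = raw.to_numpy()
    if data.shape[1] != parcellation.n_rois:
        raise CohortError(
            f"time-course file has {data.shape[1]} columns but the "
            f"parcellation defines {parcellation.n_rois} ROIs"
        )
    try:
        data = data.astype(float)
    except (TypeError, ValueError):
        for r in range(raw.shape[0]):
            for c in range(raw.shape[1]):
                try:
                    float(raw.iat[r, c])
                except (TypeError, ValueError):
                    raise CohortError(
                        f"non-numeric cell at row {r}, column {c}: {raw.iat[r, c]!r}"
                    ) from None
        raise
    if not np.isfinite(data).all():
        r, c = np.argwhere(~np.isfinite(data))[0]
        raise CohortError(f"missing/non-finite value at row {r}, column {c}")
    return ScanTimeSeries(
        data=data, tr=tr, scan_id=scan_id if scan_id is not None else path.stem
    )


def save_timeseries(ts: ScanTimeSeries, path, header: bool = True,
                    precision: int = 8) -> None:
    cols = [f"roi_{i + 1}" for i in range(ts.n_rois)]
    df = pd.DataFrame(ts.data, columns=cols)
    df.to_csv(path, sep="\t", index=False, header=header,
              float_format=f"%.{precision}g")


def load_fd(path) -> np.ndarray:
    """Read a per-frame frame-displacement trace (one value per line, mm)."""
    fd = np.loadtxt(path, dtype=float, ndmin=1)
    if (fd < 0).any():
        raise CohortError("frame displacement must be non-negative")
    return fd


def save_fd(fd: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(fd, dtype=float), fmt="%.6g")
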