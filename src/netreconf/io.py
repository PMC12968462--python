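"""Domain types and delimited-text I/O for parcellated BOLD data.

The on-disk formats are deliberately plain: tab-delimited UTF-8 text with a
header row, regions as rows and timepoints as columns for signal tables, so
fixtures can be inspected and versioned.  Writers prepend a commented header
line recording the package version and the parameters of the writing call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical resting-state networks: seven cortical systems plus one deep
#: grey matter group.  Integer community labels 1..8 follow this order.
NETWORKS = ("DMN", "FPN", "DAN", "VAN", "VN", "SMN", "LN", "DGM")

FATIGUE_SCALES = ("fatigue_total", "fatigue_motor", "fatigue_cognitive")

#: Disease-modifying treatment categories; "none" is the reference level.
DMT_CATEGORIES = (
    "none",
    "dimethyl_fumarate",
    "fingolimod",
    "glatiramer",
    "interferon",
    "natalizumab",
    "ocrelizumab",
    "siponimod",
    "teriflunomid",
)


@dataclass
class ParcellatedSeries:
    """A subject's parcellated BOLD signal: regions × timepoints.

    Parameters
    ----------
    subject_id : str
        Identifier carried through all downstream tables.
    signals : ndarray, shape (n_regions, n_timepoints)
        Real-valued signal matrix; no missing values allowed.
    tr_seconds : float
        Repetition time in seconds (sampling interval).
    region_ids : list of str
        Unique identifiers aligned with the rows of ``signals``.
    """

    subject_id: str
    signals: np.ndarray
    tr_seconds: float
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError(f"signals must be 2-D, got shape {self.signals.shape}")
        if self.signals.shape[1] < 2:
            raise ValueError("a series needs at least 2 timepoints")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.region_ids = [str(r) for r in self.region_ids]
        if len(self.region_ids) != self.signals.shape[0]:
            raise ValueError(
                f"{len(self.region_ids)} region ids for {self.signals.shape[0]} signal rows"
            )
        dupes = _duplicates(self.region_ids)
        if dupes:
            raise ValueError(f"duplicate region IDs: {sorted(dupes)}")

    @property
    def n_regions(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]


@dataclass
class AtlasLabels:
    """Mapping from region identifier to resting-state network label."""

    mapping: dict

    def __post_init__(self):
        bad = sorted({v for v in self.mapping.values()} - set(NETWORKS))
        if bad:
            raise ValueError(f"unknown network labels: {bad}; expected one of {NETWORKS}")

    def networks_present(self):
        present = {v for v in self.mapping.values()}
        return tuple(n for n in NETWORKS if n in present)

    def label_of(self, region_id: str) -> str:
        return self.mapping[region_id]

    def to_int_labels(self, region_ids) -> np.ndarray:
        """Integer community labels in 1..8 following the canonical order."""
        missing = [r for r in region_ids if r not in self.mapping]
        if missing:
            raise KeyError(f"regions without atlas label: {missing[:5]}")
        idx = {n: i + 1 for i, n in enumerate(NETWORKS)}
        return np.array([idx[self.mapping[r]] for r in region_ids], dtype=int)

    def subset(self, region_ids) -> "AtlasLabels":
        return AtlasLabels({r: self.mapping[r] for r in region_ids})


def _duplicates(items):
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _comment_header(**params) -> str:
    from netreconf import __version__

    kv = "; ".join(f"{k}={v}" for k, v in params.items())
    return f"# netreconf {__version__}" + (f"; {kv}" if kv else "")


def read_series(path, tr_seconds: float, subject_id: str | None = None,
                orientation: str = "auto") -> ParcellatedSeries:
    """Read a delimited signal table into a :class:`ParcellatedSeries`.

    The expected layout is regions as rows, first column the region ID,
    header row the timepoint index.  ``orientation`` may be ``"regions_rows"``,
    ``"regions_cols"`` or ``"auto"``; auto-detection transposes the table when
    the header is non-numeric (region IDs in the header mean regions are
    columns).  Constant-signal regions are permitted but flagged with a
    warning — they fail later, at correlation time, where the maths breaks.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", index_col=0,
                     float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty table")

    def _header_numeric(cols):
        try:
            [float(c) for c in cols]
            return True
        except (TypeError, ValueError):
            return False

    if orientation == "auto":
        orientation = "regions_rows" if _header_numeric(df.columns) else "regions_cols"
    if orientation == "regions_cols":
        df = df.T
    elif orientation != "regions_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    region_ids = [str(r) for r in df.index]
    dupes = _duplicates(region_ids)
    if dupes:
        raise ValueError(f"{path}: duplicate region IDs: {sorted(dupes)}")
    try:
        signals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [str(df.index[i]) for i in range(len(df))
               if pd.to_numeric(df.iloc[i], errors="coerce").isna().any()]
        raise ValueError(f"{path}: non-numeric cells in rows {bad[:5]}") from exc
    if np.isnan(signals).any():
        bad = [region_ids[i] for i in np.where(np.isnan(signals).any(axis=1))[0]]
        raise ValueError(f"{path}: missing or non-numeric cells in rows {bad[:5]}")

    constant = [region_ids[i] for i in np.where(signals.std(axis=1) == 0)[0]]
    if constant:
        warnings.warn(f"constant signal in regions {constant[:5]}"
                      f"{'...' if len(constant) > 5 else ''}", stacklevel=2)

    sid = subject_id if subject_id is not None else _stem(path)
    return ParcellatedSeries(sid, signals, tr_seconds, region_ids)


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_series(series: ParcellatedSeries, path) -> None:
    """Write a series as tab-delimited text (regions × timepoints)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header(subject=series.subject_id, tr_seconds=series.tr_seconds) + "\n")
        fh.write("region_id\t" + "\t".join(str(t) for t in range(series.n_timepoints)) + "\n")
        for rid, row in zip(series.region_ids, series.signals):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_atlas(path) -> AtlasLabels:
    """Read a two-column (region_id, network_label) table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: atlas needs two columns (region_id, network_label)")
    region_col, label_col = df.columns[:2]
    dupes = _duplicates(list(df[region_col]))
    if dupes:
        raise ValueError(f"{path}: duplicate region IDs: {sorted(dupes)}")
    return AtlasLabels(dict(zip(df[region_col], df[label_col])))


def write_atlas(atlas: AtlasLabels, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header() + "\n")
        fh.write("region_id\tnetwork_label\n")
        for rid, lab in atlas.mapping.items():
            fh.write(f"{rid}\t{lab}\n")


def read_coverage(path) -> pd.DataFrame:
    """Read a subjects × regions voxel-coverage table (fractions in [0, 1])."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    vals = df.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError(f"{path}: coverage fractions must lie in [0, 1]")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Read the per-subject phenotype table and validate its invariants."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    validate_phenotypes(df)
    return df


def validate_phenotypes(df: pd.DataFrame) -> None:
    if "group" not in df.columns:
        raise ValueError("phenotype table needs a 'group' column")
    bad_groups = set(df["group"].dropna()) - {"pwMS", "HC"}
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if df["group"].isna().all() or len(df) == 0:
        raise ValueError("phenotype table has no subjects with a group")
    limits = {"fatigue_total": 100.0, "fatigue_motor": 50.0, "fatigue_cognitive": 50.0}
    for col, hi in limits.items():
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce").dropna()
            if ((vals < 0) | (vals > hi)).any():
                raise ValueError(f"{col} outside [0, {hi}]")
    if "dmt_category" in df.columns:
        bad = set(df["dmt_category"].dropna()) - set(DMT_CATEGORIES)
        if bad:
            raise ValueError(f"unknown DMT categories: {sorted(bad)}")


def write_table(df: pd.DataFrame, path, **params) -> None:
    """Write any tabular output with the standard commented header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header(**params) + "\n")
        df.to_csv(fh, sep="\t")


def exclude_low_coverage(coverage: pd.DataFrame, coverage_threshold: float = 0.30,
                         subject_fraction: float = 0.10) -> list:
    """Apply the voxel-coverage exclusion rule; return retained region IDs.

    A region is excluded when the fraction of subjects whose coverage falls
    strictly below ``coverage_threshold`` is strictly greater than
    ``subject_fraction`` — i.e. "< 30% coverage in more than 10% of
    participants".  A region failing in exactly 10% of subjects is retained.
    Column order is preserved.  The rule is idempotent: filtering an
    already-filtered table removes nothing.
    """
    if coverage.size == 0:
        raise ValueError("coverage table is empty")
    vals = coverage.to_numpy(dtype=float)
    low_fraction = (vals < coverage_threshold).mean(axis=0)
    retained = [str(c) for c, f in zip(coverage.columns, low_fraction) if f <= subject_fraction]
    return retained
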