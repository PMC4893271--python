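"""Study data model and on-disk formats.

A longitudinal microbiome study is represented by :class:`Dataset`: sequencing
counts per taxon over irregular time grids for one or more subjects, paired
with total-biomass measurements (e.g. universal 16S qPCR) that restore the
absolute concentration scale lost to compositional sequencing, plus optional
binary perturbation schedules (diet shifts, antibiotics, ...).

On-disk dialect (all plain TSV):

* counts:   taxa as rows, samples as columns; first column ``taxon``.
* biomass:  columns ``sample_id``, ``biomass``; empty cell or ``NA`` = missing.
* metadata: columns ``sample_id``, ``subject``, ``day`` and one 0/1 column per
  perturbation schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PerturbationSchedule",
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "strip_biomass",
    "hide_biomass",
]

_RESERVED_META_COLS = ("sample_id", "subject", "day")


class DatasetError(ValueError):
    """Raised for malformed or inconsistent study data."""


@dataclass(frozen=True)
class PerturbationSchedule:
    """A binary on/off perturbation, as half-open day intervals per subject.

    Evaluation follows the half-open convention ``[start, end)``:
    ``u(start) = 1`` and ``u(end) = 0``.
    """

    id: str
    intervals: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for subject, ivs in self.intervals.items():
            ordered = sorted(ivs)
            for (s0, e0), (s1, _) in zip(ordered, ordered[1:]):
                if s1 < e0:
                    raise DatasetError(
                        f"perturbation {self.id!r}: overlapping intervals "
                        f"for subject {subject!r}"
                    )
            for s0, e0 in ivs:
                if not e0 > s0:
                    raise DatasetError(
                        f"perturbation {self.id!r}: empty interval "
                        f"[{s0}, {e0}) for subject {subject!r}"
                    )

    def evaluate(self, subject: str, t: float) -> int:
        """Indicator u_p(t) for one subject; always exactly 0 or 1."""
        for start, end in self.intervals.get(subject, ()):
            if start <= t < end:
                return 1
        return 0

    def switch_times(self, subject: str) -> list[float]:
        """All on/off switch points for a subject (integration breakpoints)."""
        out: list[float] = []
        for start, end in self.intervals.get(subject, ()):
            out.extend((start, end))
        return sorted(out)


@dataclass(frozen=True)
class Dataset:
    """Counts, biomass and perturbation schedules for one study.

    Attributes
    ----------
    subjects, taxa:
        Ordered labels; ``S = len(subjects)``, ``L = len(taxa)``.
    times:
        Per subject, strictly increasing sample days (length ``N_s``).
    counts:
        Per subject, integer array of shape ``(L, N_s)``.
    biomass:
        Per subject, float array of shape ``(N_s,)``; ``NaN`` marks a missing
        biomass measurement (counts are never missing: a sample either exists
        for all taxa or not at all).
    perturbations:
        Binary perturbation schedules, order defines the ``gamma`` columns.
    biomass_uninformative:
        True when biomass has been flattened to its grand mean and therefore
        carries no temporal information.
    biomass_provenance:
        Per subject, string array; "measured", "missing" or "interpolated".
    """

    subjects: tuple[str, ...]
    taxa: tuple[str, ...]
    times: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    biomass: dict[str, np.ndarray]
    perturbations: tuple[PerturbationSchedule, ...] = ()
    biomass_uninformative: bool = False
    biomass_provenance: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.taxa)
        for s in self.subjects:
            t = np.asarray(self.times[s], dtype=float)
            if t.ndim != 1 or t.size < 2:
                raise DatasetError(f"subject {s!r}: needs >= 2 time points")
            if not np.all(np.diff(t) > 0):
                raise DatasetError(f"subject {s!r}: days are not strictly increasing")
            y = np.asarray(self.counts[s])
            if y.shape != (L, t.size):
                raise DatasetError(f"subject {s!r}: counts shape {y.shape} != ({L}, {t.size})")
            if not np.issubdtype(y.dtype, np.integer):
                raise DatasetError(f"subject {s!r}: counts must be integers")
            if (y < 0).any():
                raise DatasetError(f"subject {s!r}: negative counts")
            depth = y.sum(axis=0)
            if (depth == 0).any():
                bad = int(np.flatnonzero(depth == 0)[0])
                raise DatasetError(
                    f"subject {s!r}: zero read depth at day {t[bad]:g}"
                )
            w = np.asarray(self.biomass[s], dtype=float)
            if w.shape != t.shape:
                raise DatasetError(f"subject {s!r}: biomass shape mismatch")
            present = ~np.isnan(w)
            if (w[present] <= 0).any():
                raise DatasetError(f"subject {s!r}: non-positive biomass value")
        if not self.biomass_provenance:
            object.__setattr__(
                self,
                "biomass_provenance",
                {
                    s: np.where(np.isnan(self.biomass[s]), "missing",
                                "measured").astype(object)
                    for s in self.subjects
                },
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_perturbations(self) -> int:
        return len(self.perturbations)

    def read_depth(self, subject: str) -> np.ndarray:
        """Total reads per sample (column sums of counts)."""
        return self.counts[subject].sum(axis=0)

    def n_timepoints(self, subject: str) -> int:
        return self.times[subject].size

    def biomass_values(self) -> np.ndarray:
        """All non-missing biomass values, pooled across subjects."""
        vals = np.concatenate([self.biomass[s] for s in self.subjects])
        return vals[~np.isnan(vals)]

    def perturbation_matrix(self, subject: str, days: np.ndarray) -> np.ndarray:
        """Indicator matrix u[p, t] evaluated on the given days."""
        days = np.asarray(days, dtype=float)
        return np.array(
            [[p.evaluate(subject, d) for d in days] for p in self.perturbations],
            dtype=float,
        ).reshape(len(self.perturbations), days.size)


# -- I/O ------------------------------------------------------------------


def _parse_counts(counts_path) -> pd.DataFrame:
    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DatasetError("counts table needs a taxon column plus >=1 sample column")
    df = df.set_index(df.columns[0])
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise DatasetError(f"counts column {col!r}: non-numeric entry") from exc
        if not np.allclose(vals, np.round(vals)):
            bad = df.index[~np.isclose(vals, np.round(vals))][0]
            raise DatasetError(
                f"counts: non-integer value at row {bad!r}, column {col!r}"
            )
        out[col] = vals.astype(np.int64)
    return out


def read_dataset(counts_path, biomass_path, metadata_path) -> Dataset:
    """Read and validate a study from counts / biomass / metadata TSVs.

    Samples are ordered by day within subject; duplicate ``(subject, day)``
    pairs are rejected.  Biomass may be missing (empty cell or ``NA``);
    counts may not.
    """
    counts = _parse_counts(counts_path)
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in _RESERVED_META_COLS:
        if col not in meta.columns:
            raise DatasetError(f"metadata: missing required column {col!r}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta = meta.set_index("sample_id")

    biomass = pd.read_csv(biomass_path, sep="\t", na_values=["NA", ""])
    if "sample_id" not in biomass.columns or "biomass" not in biomass.columns:
        raise DatasetError("biomass table: need columns sample_id, biomass")
    biomass["sample_id"] = biomass["sample_id"].astype(str)
    wmap = biomass.set_index("sample_id")["biomass"].astype(float)

    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise DatasetError(f"samples in counts but not in metadata: {missing}")

    pert_cols = [c for c in meta.columns if c not in ("subject", "day")]
    subjects = tuple(dict.fromkeys(meta.loc[list(counts.columns), "subject"].astype(str)))
    taxa = tuple(counts.index)

    times: dict[str, np.ndarray] = {}
    ymat: dict[str, np.ndarray] = {}
    wvec: dict[str, np.ndarray] = {}
    pert_intervals: dict[str, dict[str, list[tuple[float, float]]]] = {
        p: {} for p in pert_cols
    }
    for s in subjects:
        samp = [c for c in counts.columns if str(meta.loc[c, "subject"]) == s]
        days = np.array([float(meta.loc[c, "day"]) for c in samp])
        order = np.argsort(days, kind="stable")
        days = days[order]
        samp = [samp[i] for i in order]
        if np.unique(days).size != days.size:
            raise DatasetError(f"subject {s!r}: duplicate (subject, day) sample")
        times[s] = days
        ymat[s] = counts[samp].to_numpy()
        wvec[s] = np.array([wmap.get(c, np.nan) for c in samp], dtype=float)
        for p in pert_cols:
            flags = np.array([int(meta.loc[c, p]) for c in samp])
            pert_intervals[p][s] = _flags_to_intervals(days, flags)

    perts = tuple(
        PerturbationSchedule(id=p, intervals={
            s: tuple(iv) for s, iv in pert_intervals[p].items() if iv
        })
        for p in pert_cols
    )
    return Dataset(
        subjects=subjects, taxa=taxa, times=times, counts=ymat, biomass=wvec,
        perturbations=perts,
    )


def _flags_to_intervals(days: np.ndarray, flags: np.ndarray) -> list[tuple[float, float]]:
    """Convert per-sample 0/1 flags into half-open on-intervals.

    An interval opens at the first flagged day and closes at the first
    subsequent unflagged day (or just past the final day if still on).
    """
    intervals: list[tuple[float, float]] = []
    start: float | None = None
    for d, f in zip(days, flags):
        if f and start is None:
            start = float(d)
        elif not f and start is not None:
            intervals.append((start, float(d)))
            start = None
    if start is not None:
        intervals.append((start, float(days[-1]) + 1.0))
    return intervals


def write_dataset(ds: Dataset, counts_path, biomass_path, metadata_path) -> None:
    """Write a dataset back to the three-TSV dialect (round-trip exact)."""
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    w_rows = []
    for s in ds.subjects:
        for j, day in enumerate(ds.times[s]):
            sid = f"{s}_d{day:g}"
            cols[sid] = ds.counts[s][:, j]
            row = {"sample_id": sid, "subject": s, "day": day}
            for p in ds.perturbations:
                row[p.id] = p.evaluate(s, day)
            meta_rows.append(row)
            w = ds.biomass[s][j]
            w_rows.append({"sample_id": sid,
                           "biomass": "" if np.isnan(w) else repr(float(w))})
    cdf = pd.DataFrame(cols, index=pd.Index(ds.taxa, name="taxon"))
    cdf.to_csv(counts_path, sep="\t")
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)
    pd.DataFrame(w_rows).to_csv(biomass_path, sep="\t", index=False)


# -- transforms -----------------------------------------------------------


def strip_biomass(ds: Dataset) -> Dataset:
    """Replace every biomass value by the grand mean over all present values.

    Emulates the "no biomass" robustness experiment: the scale survives but
    the temporal signal is destroyed.  Idempotent.
    """
    vals = ds.biomass_values()
    if vals.size == 0:
        raise DatasetError("strip_biomass: all biomass values are missing")
    mean = float(vals.mean())
    return replace(
        ds,
        biomass={s: np.full(ds.times[s].size, mean) for s in ds.subjects},
        biomass_uninformative=True,
        biomass_provenance={
            s: np.full(ds.times[s].size, "measured", dtype=object)
            for s in ds.subjects
        },
    )


def hide_biomass(ds: Dataset, hidden: set[tuple[str, float]]) -> Dataset:
    """Flag the biomass of the given ``(subject, day)`` samples as missing."""
    new_w = {s: ds.biomass[s].copy() for s in ds.subjects}
    new_prov = {s: ds.biomass_provenance[s].copy() for s in ds.subjects}
    for subject, day in hidden:
        if subject not in ds.times:
            raise KeyError(f"unknown subject {subject!r}")
        idx = np.flatnonzero(np.isclose(ds.times[subject], day))
        if idx.size == 0:
            raise KeyError(f"no sample at (subject={subject!r}, day={day!r})")
        new_w[subject][idx[0]] = np.nan
        new_prov[subject][idx[0]] = "missing"
    return replace(ds, biomass=new_w, biomass_provenance=new_prov)
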