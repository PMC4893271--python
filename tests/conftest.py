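import numpy as np
import pytest

from glvinfer.dataset import Dataset, PerturbationSchedule
from glvinfer.model import GLVParameters, integrate
from glvinfer.trajectories import TrajectoryEstimate


@pytest.fixture
def toy_files(tmp_path):
    """Three-taxa, two-subject, four-timepoint study on disk (TSV dialect)."""
    counts = tmp_path / "counts.tsv"
    biomass = tmp_path / "biomass.tsv"
    metadata = tmp_path / "metadata.tsv"
    counts.write_text(
        "taxon\tm1_d0\tm1_d1\tm1_d2\tm1_d4\tm2_d0\tm2_d1\tm2_d2\tm2_d4\n"
        "A\t10\t20\t30\t40\t12\t22\t32\t42\n"
        "B\t50\t40\t30\t20\t48\t38\t28\t18\n"
        "C\t40\t40\t40\t40\t40\t40\t40\t40\n"
    )
    biomass.write_text(
        "sample_id\tbiomass\n"
        "m1_d0\t2.0\nm1_d1\t2.5\nm1_d2\t3.0\nm1_d4\t3.5\n"
        "m2_d0\t2.1\nm2_d1\t2.6\nm2_d2\t3.1\nm2_d4\t3.6\n"
    )
    metadata.write_text(
        "sample_id\tsubject\tday\tdiet\n"
        "m1_d0\tm1\t0\t0\nm1_d1\tm1\t1\t1\nm1_d2\tm1\t2\t1\nm1_d4\tm1\t4\t0\n"
        "m2_d0\tm2\t0\t0\nm2_d1\tm2\t1\t1\nm2_d2\tm2\t2\t1\nm2_d4\tm2\t4\t0\n"
    )
    return counts, biomass, metadata


def make_dataset(counts_by_subject, biomass_by_subject, times_by_subject,
                 taxa=None, perturbations=()):
    subjects = tuple(counts_by_subject)
    first = next(iter(counts_by_subject.values()))
    L = np.asarray(first).shape[0]
    return Dataset(
        subjects=subjects,
        taxa=taxa or tuple(f"t{i}" for i in range(L)),
        times={s: np.asarray(t, dtype=float) for s, t in times_by_subject.items()},
        counts={s: np.asarray(c, dtype=np.int64) for s, c in counts_by_subject.items()},
        biomass={s: np.asarray(w, dtype=float) for s, w in biomass_by_subject.items()},
        perturbations=perturbations,
    )


@pytest.fixture
def simple_dataset():
    """Two subjects, three taxa, four days, no perturbations."""
    days = [0.0, 1.0, 2.0, 4.0]
    y = [[10, 20, 30, 40], [50, 40, 30, 20], [40, 40, 40, 40]]
    return make_dataset(
        {"m1": y, "m2": y},
        {"m1": [2.0, 2.5, 3.0, 3.5], "m2": [2.0, 2.5, 3.0, 3.5]},
        {"m1": days, "m2": days},
    )


def exact_trajectory_estimate(params: GLVParameters, x0, grid,
                              subjects=("s1",), schedules=(), ds=None):
    """Noise-free trajectory + exact model gradients (oracle input)."""
    grid = np.asarray(grid, dtype=float)
    f, fp, g = {}, {}, {}
    for s in subjects:
        traj = integrate(params, x0, schedules, grid, subject=None if not schedules else s)
        if ds is not None and params.n_perturbations:
            u = ds.perturbation_matrix(s, grid)
        else:
            u = np.zeros((params.n_perturbations, grid.size))
        growth = (params.alpha[:, None] + params.beta @ traj
                  + params.gamma @ u)
        f[s], fp[s], g[s] = traj, traj * growth, grid
    return TrajectoryEstimate(grid=g, f=f, fprime=fp)


class MinimalDS:
    """Dataset stand-in offering just what gradient matching needs."""

    def __init__(self, subjects=("s1",), n_taxa=3, perturbations=()):
        self.subjects = tuple(subjects)
        self.n_taxa = n_taxa
        self.perturbations = tuple(perturbations)
        self.n_perturbations = len(self.perturbations)

    def perturbation_matrix(self, s, days):
        days = np.asarray(days, dtype=float)
        return np.array(
            [[p.evaluate(s, d) for d in days] for p in self.perturbations]
        ).reshape(self.n_perturbations, days.size)


@pytest.fixture
def three_taxa_params():
    return GLVParameters(
        alpha=np.array([1.0, 0.8, 1.2]),
        beta=np.array([
            [-1.0, 0.1, 0.0],
            [0.0, -0.9, 0.2],
            [-0.1, 0.0, -1.1],
        ]),
    )
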