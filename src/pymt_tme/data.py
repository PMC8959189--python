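"""The three-mouse PyMT time-course dataset and its normalization.

Ships the processed per-mouse cell/cytokine abundances (three PyMT mice
sampled at weeks 6, 8, 10 and 12 of tumor progression; the 6-week sample
is taken as the time origin, so the sampling days are 0, 14, 28 and 42).
Cell rows come from immune deconvolution of bulk RNA-seq plus
tumor-size-based estimates of cancer/necrotic/adipocyte counts; cytokine
rows are gene-expression scores.  All values are in the arbitrary
abundance units of the source study.

Also hosts the nondimensionalization (divide each variable by its
maximum over all mice and time points) and the tumor-composition
calculator that converts tumor sizes and immune-cell ratios into total
cell counts using the 0.955 : 0.04 : 0.005 cancer : immune : necrotic
ratio and the epithelial density scaling ``alpha = 45``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ode import N_VARS, VAR_NAMES

__all__ = [
    "MouseTimeSeries",
    "StudyDataset",
    "NormalizationScales",
    "TumorComposition",
    "builtin_dataset",
    "compute_scales",
    "nondimensionalize",
    "redimensionalize",
    "estimate_composition",
]

SAMPLING_DAYS = (0.0, 14.0, 28.0, 42.0)

# Per-mouse rows: day -> (T_N, T_h, T_c, T_r, D_N, D, M_N, M,
#                         C, N, A, H, IL12, IL10, IL6)
_STUDY_TABLE = {
    1: {
        0:  (18.91552, 0.180307, 0.001385, 0.120725, 13.04028, 0.498882,
             6.767523, 7.386616, 6.56815, 0.034388, 93.82247,
             1000, 28, 417, 2490),
        14: (6.771898, 0.673464, 4.279462, 0.001385, 8.607666, 0.001385,
             6.115784, 15.72747, 32.33359, 0.169286, 84.35702,
             940, 24, 351, 1766),
        28: (16.02047, 0.001385, 0.164525, 0.269144, 6.955235, 0.001385,
             6.053538, 19.64027, 57.61312, 0.301639, 98.2119,
             1103, 0, 404, 1599),
        42: (8.807364, 0.073352, 2.217549, 0.001385, 11.31217, 0.313571,
             1.842909, 17.24431, 83.48514, 0.437095, 83.62523,
             1050, 2, 455, 1880),
    },
    2: {
        0:  (14.18682, 0.001459, 0.001459, 0.001459, 8.67344, 0.001459,
             14.50968, 9.00316, 6.590515, 0.034505, 92.75787,
             1182, 0, 450, 1602),
        14: (2.54051, 0.787626, 0.001459, 0.001459, 13.30604, 0.001459,
             26.56551, 0.632713, 32.26456, 0.168924, 87.67355,
             932, 16, 723, 1068),
        28: (7.022259, 0.444987, 2.773333, 0.001459, 14.39057, 0.001459,
             21.57876, 4.581648, 57.54278, 0.301271, 101.5889,
             945, 0, 429, 1646),
        42: (11.05377, 0.001459, 3.951772, 0.001459, 8.180317, 0.001459,
             7.14771, 8.669383, 83.60215, 0.437708, 78.01466,
             807, 0, 319, 1490),
    },
    3: {
        0:  (10.84328, 0.014559, 2.398143, 0.14663, 11.10196, 0.466044,
             9.302918, 8.559201, 6.73803, 0.035278, 85.66546,
             1521, 19, 511, 3327),
        14: (11.18575, 0.748596, 0.235111, 0.001456, 11.90139, 0.001456,
             6.080938, 16.72823, 32.13758, 0.16826, 93.76585,
             1549, 3, 566, 3481),
        28: (17.73009, 0.001456, 0.608837, 0.001456, 12.19168, 0.001456,
             6.812254, 6.448463, 57.83445, 0.302798, 87.59139,
             957, 0, 349, 1716),
        42: (10.89853, 1.288033, 0.552229, 0.001456, 12.57453, 0.001456,
             13.96522, 7.217389, 83.28994, 0.436073, 92.99769,
             779, 4, 278, 1490),
    },
}


@dataclass(frozen=True)
class MouseTimeSeries:
    """Abundance time course of one mouse: ``values[i, j]`` is variable
    ``VAR_NAMES[j]`` at ``times[i]`` days."""

    mouse_id: int
    times: np.ndarray
    values: np.ndarray
    frame: str = "dimensional"  # or "nondimensional"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (t.size, N_VARS):
            raise ValueError(f"values must be (n_times, {N_VARS})")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("abundances must be nonnegative")
        if self.frame not in ("dimensional", "nondimensional"):
            raise ValueError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def state_at(self, day: float) -> np.ndarray:
        i = np.flatnonzero(self.times == day)
        if i.size == 0:
            raise KeyError(f"no sample at day {day}")
        return self.values[i[0]].copy()


@dataclass(frozen=True)
class StudyDataset:
    """A set of mouse time courses sharing frame and variable layout."""

    mice: tuple[MouseTimeSeries, ...]

    def __post_init__(self):
        if not self.mice:
            raise ValueError("dataset has no mice")
        frames = {m.frame for m in self.mice}
        if len(frames) > 1:
            raise ValueError("mixed dimensional/nondimensional mice")

    @property
    def frame(self) -> str:
        return self.mice[0].frame

    def __iter__(self):
        return iter(self.mice)

    def __len__(self) -> int:
        return len(self.mice)

    def mouse(self, mouse_id: int) -> MouseTimeSeries:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m
        raise KeyError(f"no mouse {mouse_id}")

    # -- tabular I/O (long format: one row per (mouse, day)) ---------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.mice:
            for t, vals in zip(m.times, m.values):
                rows.append({"mouse": m.mouse_id, "day": int(t)
                             if float(t).is_integer() else float(t),
                             **dict(zip(VAR_NAMES, vals))})
        return pd.DataFrame(rows, columns=["mouse", "day", *VAR_NAMES])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       frame: str = "dimensional") -> "StudyDataset":
        missing = set(("mouse", "day", *VAR_NAMES)) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        mice = []
        for mid, grp in df.groupby("mouse", sort=True):
            grp = grp.sort_values("day")
            mice.append(MouseTimeSeries(
                int(mid), grp["day"].to_numpy(float),
                grp[list(VAR_NAMES)].to_numpy(float), frame))
        return cls(tuple(mice))

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, frame: str = "dimensional") -> "StudyDataset":
        return cls.from_dataframe(pd.read_csv(path_or_buf), frame)


def builtin_dataset() -> StudyDataset:
    """The embedded three-mouse dataset, in printed (dimensional) units."""
    mice = []
    for mid, rows in _STUDY_TABLE.items():
        days = sorted(rows)
        vals = np.array([rows[d] for d in days], dtype=float)
        mice.append(MouseTimeSeries(mid, np.array(days, float), vals))
    return StudyDataset(tuple(mice))


@dataclass(frozen=True)
class NormalizationScales:
    """Per-variable scales X_inf used for nondimensionalization."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_VARS,):
            raise ValueError(f"need {N_VARS} scales")
        if np.any(v <= 0):
            raise ValueError("scales must be positive")
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[VAR_NAMES.index(name)])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(zip(VAR_NAMES, map(float, self.values))), fh,
                      indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "NormalizationScales":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array([d[n] for n in VAR_NAMES], float))


def compute_scales(dataset: StudyDataset) -> NormalizationScales:
    """Per-variable maximum over all mice and time points."""
    if dataset.frame != "dimensional":
        raise ValueError("scales are computed from the dimensional frame")
    stacked = np.vstack([m.values for m in dataset])
    scales = stacked.max(axis=0)
    if np.any(scales <= 0):
        bad = [VAR_NAMES[i] for i in np.where(scales <= 0)[0]]
        raise ValueError(f"all-zero variable column(s): {bad}")
    return NormalizationScales(scales)


def nondimensionalize(dataset: StudyDataset,
                      scales: NormalizationScales) -> StudyDataset:
    if dataset.frame != "dimensional":
        raise ValueError("dataset is already nondimensional")
    return StudyDataset(tuple(
        replace(m, values=m.values / scales.values, frame="nondimensional")
        for m in dataset))


def redimensionalize(dataset: StudyDataset,
                     scales: NormalizationScales) -> StudyDataset:
    if dataset.frame != "nondimensional":
        raise ValueError("dataset is already dimensional")
    return StudyDataset(tuple(
        replace(m, values=m.values * scales.values, frame="dimensional")
        for m in dataset))


# --------------------------------------------------------------------------
# Tumor composition: from tumor sizes and immune-cell ratios to cell counts
# --------------------------------------------------------------------------

#: cancer : immune : necrotic composition of the mouse breast tumors
COMPOSITION_RATIOS = (0.955, 0.04, 0.005)

#: epithelial-cell density scaling (cells/mm^3)
ALPHA_DEFAULT = 45.0


@dataclass(frozen=True)
class TumorComposition:
    """Per-time-point total/immune/cancer/necrotic cell counts.

    ``TNCC/TNNC = 0.955/0.005 = 191`` exactly, and the three components
    add back up to the total: ``TNCC + TNNC + TNIC = TNC``.
    """

    times: np.ndarray
    TNC: np.ndarray
    TNIC: np.ndarray
    TNCC: np.ndarray
    TNNC: np.ndarray
    alpha: float = ALPHA_DEFAULT
    ratios: tuple[float, float, float] = COMPOSITION_RATIOS

    def to_json(self, path) -> None:
        d = {"alpha": self.alpha, "ratios": list(self.ratios)}
        for k in ("times", "TNC", "TNIC", "TNCC", "TNNC"):
            d[k] = [float(v) for v in getattr(self, k)]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TumorComposition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(*(np.asarray(d[k], float) for k in
                     ("times", "TNC", "TNIC", "TNCC", "TNNC")),
                   alpha=d["alpha"], ratios=tuple(d["ratios"]))


def estimate_composition(tumor_sizes, immune_ratios, times=SAMPLING_DAYS,
                         alpha: float = ALPHA_DEFAULT,
                         ratios=COMPOSITION_RATIOS) -> TumorComposition:
    """Convert tumor sizes and immune-cell ratios into cell counts.

    ``TNC_i = alpha * size(t_i) / mean(size)`` and, analogously,
    ``TNIC_i = (immune fraction) * alpha * ratio(t_i) / mean(ratio)``.
    The cancer and necrotic counts then split the remainder in the
    0.955 : 0.005 proportion (the 191/192 fraction).
    """
    sizes = np.asarray(tumor_sizes, dtype=float)
    imm = np.asarray(immune_ratios, dtype=float)
    times = np.asarray(times, dtype=float)
    if sizes.shape != times.shape or imm.shape != times.shape:
        raise ValueError("sizes, ratios and times must have equal length")
    if np.any(sizes <= 0):
        raise ValueError("tumor sizes must be positive")
    if np.any(imm < 0):
        raise ValueError("immune ratios must be nonnegative")
    r_c, r_i, r_n = ratios
    if abs(r_c + r_i + r_n - 1.0) > 1e-12:
        raise ValueError("composition ratios must sum to 1")
    TNC = alpha * sizes / sizes.mean()
    TNIC = r_i * alpha * imm / imm.mean()
    frac = r_c / (r_c + r_n)  # 191/192 for the default ratios
    TNCC = frac * (TNC - TNIC)
    TNNC = TNCC * (r_n / r_c)
    return TumorComposition(times, TNC, TNIC, TNCC, TNNC, alpha,
                            tuple(ratios))
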