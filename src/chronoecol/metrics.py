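"""Summary statistics, the cross-group mating (CGM) statistic, and the
per-trial record.

The CGM quantifies reproductive segregation of a population whose mating
is assortative by phase angle.  From the pairwise mating-window overlap
matrix ``M`` (symmetric, unit diagonal, values in [0, 1]) the population
is split into two clusters by 2-means on the rows of ``M``; the CGM is the
mean overlap between individuals of different clusters — equivalently the
probability that a given mating crosses the cluster boundary.  CGM = 1
means one panmictic group, CGM = 0 complete reproductive isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rhythm
from .reproduction import mating_window_overlap

__all__ = [
    "overlap_matrix",
    "cgm",
    "species_phase_difference",
    "circular_sd",
    "CIRCULAR_SD_CAP",
    "detect_exclusion",
    "detect_speciation",
    "resource_time_histogram",
    "TrialRecord",
    "config_hash",
]

_R_FLOOR = 1e-12
#: Ceiling on the circular SD (degrees), reached when the mean resultant
#: length underflows `_R_FLOOR` (an effectively uniform phase distribution).
CIRCULAR_SD_CAP = float(np.sqrt(-2.0 * np.log(_R_FLOOR)) * 180.0 / np.pi)

_KMEANS_RESTARTS = 10
_KMEANS_MAX_ITER = 300
_KMEANS_TOL = 1e-6


def overlap_matrix(phases, width: float = 135.0) -> np.ndarray:
    """Pairwise mating-window overlap matrix M_ij (symmetric, unit diagonal)."""
    p = np.asarray(phases, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one phase")
    d = np.abs(p[:, None] - p[None, :]) % 360.0
    d = np.minimum(d, 360.0 - d)
    return np.maximum(0.0, (width - d) / width)


def _lloyd_2means(x: np.ndarray, rng, max_iter: int = _KMEANS_MAX_ITER,
                  tol: float = _KMEANS_TOL):
    """One restart of Lloyd's algorithm with k = 2 on the rows of ``x``.

    Centers are initialized at two distinct random rows.  Returns
    (labels, within-cluster sum of squares), or None if a cluster emptied.
    """
    n = x.shape[0]
    i, j = rng.choice(n, size=2, replace=False)
    centers = x[[i, j]].copy()
    sq = (x * x).sum(axis=1)
    labels = None
    for _ in range(max_iter):
        d2 = sq[:, None] - 2.0 * (x @ centers.T) + (centers * centers).sum(axis=1)
        labels = np.argmin(d2, axis=1)
        if labels.min() == labels.max():  # one cluster emptied
            return None
        new_centers = np.stack([x[labels == 0].mean(axis=0),
                                x[labels == 1].mean(axis=0)])
        shift = float(((new_centers - centers) ** 2).sum())
        centers = new_centers
        if shift < tol:
            break
    inertia = 0.0
    for c in (0, 1):
        inertia += float(((x[labels == c] - centers[c]) ** 2).sum())
    return labels, inertia


def cgm(phases, rng=None, width: float = 135.0,
        n_restarts: int = _KMEANS_RESTARTS, return_labels: bool = False):
    """Cross-group mating statistic of a population of phase angles.

    2-means clustering (Lloyd's algorithm, ``n_restarts`` seeded restarts,
    best within-cluster sum of squares kept) on the rows of the overlap
    matrix defines two mating groups; the CGM is the mean overlap between
    members of different groups.  Undefined (None) for fewer than two
    organisms.  A population of identical rows cannot support two
    non-empty clusters; the split is then arbitrary and every overlap is
    identical, so the common overlap value is returned.
    """
    p = np.asarray(phases, dtype=float)
    if p.size < 2:
        return (None, None) if return_labels else None
    if rng is None:
        rng = np.random.default_rng(0)
    m = overlap_matrix(p, width)
    best = None
    best_inertia = np.inf
    for _ in range(n_restarts):
        out = None
        for _retry in range(5):  # re-initialize a restart that emptied a cluster
            out = _lloyd_2means(m, rng)
            if out is not None:
                break
        if out is None:
            continue
        labels, inertia = out
        if inertia < best_inertia:
            best_inertia = inertia
            best = labels
    if best is None:
        # All rows identical: arbitrary split, all cross overlaps equal.
        best = np.zeros(p.size, dtype=np.int64)
        best[0] = 1
    cross = m[np.ix_(best == 0, best == 1)]
    value = float(cross.mean())
    return (value, best) if return_labels else value


def species_phase_difference(phases_a, phases_b) -> float:
    """Circular distance between two populations' circular mean phases."""
    return rhythm.circular_distance(
        rhythm.circular_mean(phases_a), rhythm.circular_mean(phases_b)
    )


def circular_sd(phases) -> float:
    """Circular standard deviation sqrt(-2 ln R) of phases, in degrees.

    ``R`` is the mean resultant length.  Diverges as the distribution
    approaches uniformity; capped at :data:`CIRCULAR_SD_CAP`.
    """
    p = np.asarray(phases, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two phases")
    rad = p * np.pi / 180.0
    r = float(np.hypot(np.cos(rad).mean(), np.sin(rad).mean()))
    if r < _R_FLOOR:
        return CIRCULAR_SD_CAP
    if r >= 1.0:
        return 0.0
    return float(np.sqrt(-2.0 * np.log(r)) * 180.0 / np.pi)


def detect_exclusion(populations: pd.DataFrame):
    """Earliest day at which any species' population reaches zero.

    ``populations``: tidy frame with columns day, species, population.
    Returns (day, [species indices extinct on that day]) or None.
    """
    zero = populations[populations["population"] == 0]
    if zero.empty:
        return None
    first = zero.groupby("species")["day"].min()
    day = int(first.min())
    return day, sorted(int(s) for s in first[first == day].index)


def detect_speciation(cgm_series: pd.Series, threshold: float = 0.1):
    """First day with CGM below ``threshold``; None if never reached."""
    s = cgm_series.dropna()
    below = s[s < threshold]
    if below.empty:
        return None
    return int(below.index[0])


def resource_time_histogram(record: "TrialRecord") -> pd.DataFrame:
    """Per-day 10-bin time-of-day profile of total grid resources.

    One row per day; column ``res_bin_b`` is the total resource count on
    the grid at the end of time step ``b`` of that day.
    """
    cols = [c for c in record.df.columns if c.startswith("res_bin_")]
    return record.df.drop_duplicates("day").set_index("day")[cols]


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration (canonical-JSON SHA-256)."""
    blob = json.dumps(config_dict, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TrialRecord:
    """Everything recorded from one simulated trial.

    df : tidy frame, one row per day per species, with columns
         day, species, population, mean_amplitude, phase_mean, phase_sd,
         cgm (population-level, NaN when not computed), res_bin_0..9
         (population-level resource snapshots, repeated across species).
    events : exclusion_day (per species or None), speciation_day,
             horizon_reached.
    organisms : optional final-day per-organism sample with columns
         species, rel_phase (signed degrees from the species' circular
         mean), energy.
    """

    df: pd.DataFrame
    events: dict
    config: dict
    seed: int
    organisms: pd.DataFrame | None = None

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)

    def final_populations(self) -> dict:
        last = self.df[self.df["day"] == self.df["day"].max()]
        return {int(r.species): int(r.population) for r in last.itertuples()}

    def write(self, out_dir, stem: str = "trial") -> dict:
        """Write the record as ``<stem>.csv`` plus a JSON sidecar with the
        events, seed, and a config echo; returns the paths written."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{stem}.csv"
        self.df.to_csv(csv_path, index=False, float_format="%.17g")
        paths = {"csv": csv_path}
        if self.organisms is not None:
            org_path = out_dir / f"{stem}_organisms.csv"
            self.organisms.to_csv(org_path, index=False, float_format="%.17g")
            paths["organisms"] = org_path
        sidecar = {
            "seed": int(self.seed),
            "config": self.config,
            "config_hash": self.config_hash,
            "events": self.events,
        }
        json_path = out_dir / f"{stem}.json"
        json_path.write_text(json.dumps(sidecar, indent=2, default=float))
        paths["json"] = json_path
        return paths

    @classmethod
    def read(cls, out_dir, stem: str = "trial") -> "TrialRecord":
        """Round-trip counterpart of :meth:`write`."""
        out_dir = Path(out_dir)
        df = pd.read_csv(out_dir / f"{stem}.csv", float_precision="round_trip")
        sidecar = json.loads((out_dir / f"{stem}.json").read_text())
        org_path = out_dir / f"{stem}_organisms.csv"
        organisms = (pd.read_csv(org_path, float_precision="round_trip")
                     if org_path.exists() else None)
        return cls(df=df, events=sidecar["events"], config=sidecar["config"],
                   seed=sidecar["seed"], organisms=organisms)
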