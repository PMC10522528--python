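"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a preoperative glioblastoma cohort: per-subject
resting-state BOLD matrices with planted network-coupling structure,
contralesional cortical-thickness tables over 34 Desikan-Killiany parcels
with group-dependent thinning, group-dependent demographics, and survival
times consistent with the three prognosis classes (<1 y, 1-2 y, >2 y).

The BOLD model is deliberately minimal: each network has one latent time
course, latents are jointly Gaussian with covariance equal to the group's
network-coupling matrix, and every voxel is its network's latent plus iid
Gaussian noise.  Under this model the between-network distance correlation
is monotone in the planted coupling, which is exactly the property the
downstream pipeline must recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import CANONICAL_NETWORKS, ProbabilityMap, TimeSeriesSet
from .errors import ConfigurationError

#: Survival classes in worst-to-best prognosis order.
CLASSES: tuple[str, ...] = ("LT1Y", "Y1TO2", "GT2Y")

#: Class boundaries in months; 12 and 24 themselves fall in the middle class.
CLASS_BOUNDS: tuple[float, float] = (12.0, 24.0)

#: Upper limit (months) for generated long-survivor times.
MAX_SURVIVAL_MONTHS = 120.0

#: Plausible mean cortical thickness (mm) for 34 Desikan-Killiany parcels.
DEFAULT_CT_BASELINE: tuple[float, ...] = (
    2.61, 2.95, 2.73, 2.38, 2.84, 2.46, 2.69, 2.87, 2.52, 2.77,
    2.23, 1.96, 2.66, 2.91, 3.05, 2.41, 2.58, 2.34, 2.71, 2.89,
    2.47, 2.63, 2.99, 2.28, 2.55, 2.81, 2.43, 2.75, 2.93, 2.36,
    2.67, 2.49, 3.12, 2.59,
)

#: Network pairs (canonical indices) carrying group-dependent coupling by
#: default: SMD-CON, SMD-VIS, SMI-PMN.
DEFAULT_PLANTED_PAIRS: tuple[tuple[int, int], ...] = ((0, 2), (0, 6), (1, 5))


def _nearest_correlation(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, V = np.linalg.eigh(C)
    if w.min() >= 1e-10:
        return C
    Cp = (V * np.maximum(w, 1e-8)) @ V.T
    d = np.sqrt(np.diag(Cp))
    return Cp / np.outer(d, d)


def default_coupling_matrices(
    n_networks: int = 15,
    baseline: float = 0.15,
    planted_pairs: Sequence[tuple[int, int]] = DEFAULT_PLANTED_PAIRS,
    coupling_by_group: Sequence[float] = (0.75, 0.45, 0.15),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-group coupling matrices with group signal in a few pairs.

    Every off-diagonal entry starts at ``baseline``; the planted pairs are
    raised to the group's coupling level (worst-prognosis group first, so the
    default plants the strongest coupling disruption signal as *higher*
    coupling in short survivors).  Matrices are projected to the nearest
    correlation matrix so latent sampling is well defined.
    """
    planted_pairs = [p for p in planted_pairs if max(p) < n_networks]
    out = []
    for level in coupling_by_group:
        C = np.full((n_networks, n_networks), baseline)
        np.fill_diagonal(C, 1.0)
        for i, j in planted_pairs:
            if i == j:
                raise ConfigurationError("planted pairs must be between-network")
            C[i, j] = C[j, i] = level
        out.append(_nearest_correlation(C))
    return tuple(out)  # type: ignore[return-value]


@dataclass
class SimConfig:
    """Everything the cohort generator needs, with study-scale defaults.

    Groups are ordered (LT1Y, Y1TO2, GT2Y) throughout.  Defaults emulate the
    study conditions: 15 networks x 200 voxels, ~320 BOLD frames over two
    concatenated runs, cohort mean age near 61 with short survivors older,
    a male-leaning sex ratio, and per-class lognormal survival scales whose
    medians sit inside the class intervals.
    """

    n_subjects: int = 133
    group_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_networks: int = 15
    voxels_per_network: int = 200
    n_frames: int = 320
    coupling_matrices: tuple[np.ndarray, ...] | None = None
    noise_sd: float = 1.0
    ct_baseline: tuple[float, ...] = DEFAULT_CT_BASELINE
    ct_group_shift: tuple[float, float, float] = (-0.15, 0.0, 0.15)
    ct_noise_sd: float = 0.12
    age_mean_by_group: tuple[float, float, float] = (65.0, 61.0, 57.0)
    age_sd: float = 10.0
    sex_prob_by_group: tuple[float, float, float] = (0.64, 0.58, 0.50)
    survival_scale_by_group: tuple[float, float, float] = (8.0, 17.0, 34.0)
    survival_log_sd: float = 0.45
    censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        for name in ("n_networks", "voxels_per_network", "n_frames"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        props = np.asarray(self.group_proportions, float)
        if props.shape != (3,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("group_proportions must be 3 non-negative fractions summing to 1")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        if len(self.ct_baseline) != 34 or any(v <= 0 for v in self.ct_baseline):
            raise ConfigurationError("ct_baseline must be 34 positive thicknesses (mm)")
        if any(s <= 0 for s in self.survival_scale_by_group):
            raise ConfigurationError("survival scales must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        if self.coupling_matrices is None:
            self.coupling_matrices = default_coupling_matrices(self.n_networks)
        mats = []
        for g, C in enumerate(self.coupling_matrices):
            C = np.asarray(C, float)
            if C.shape != (self.n_networks, self.n_networks):
                raise ConfigurationError(f"coupling matrix {g}: wrong shape {C.shape}")
            if not np.allclose(C, C.T, atol=1e-12):
                raise ConfigurationError(f"coupling matrix {g}: not symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-12):
                raise ConfigurationError(f"coupling matrix {g}: diagonal must be 1")
            if C.min() < 0.0 or C.max() > 1.0 + 1e-12:
                raise ConfigurationError(f"coupling matrix {g}: entries outside [0, 1]")
            mats.append(C)
        self.coupling_matrices = tuple(mats)

    @property
    def networks(self) -> tuple[str, ...]:
        if self.n_networks <= len(CANONICAL_NETWORKS):
            return CANONICAL_NETWORKS[: self.n_networks]
        return CANONICAL_NETWORKS + tuple(
            f"NET{i:02d}" for i in range(len(CANONICAL_NETWORKS), self.n_networks)
        )


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: int  # 0 = female, 1 = male
    ct: np.ndarray  # 34 contralesional Desikan-Killiany thicknesses (mm)
    survival_months: float
    event: int
    survival_class: str

    def __post_init__(self) -> None:
        lo, hi = CLASS_BOUNDS
        t = self.survival_months
        expected = "LT1Y" if t < lo else ("Y1TO2" if t <= hi else "GT2Y")
        if self.survival_class != expected:
            raise ConfigurationError(
                f"{self.subject_id}: class {self.survival_class} inconsistent with "
                f"{t:.2f} months"
            )
        if np.any(np.asarray(self.ct) <= 0):
            raise ConfigurationError(f"{self.subject_id}: non-positive cortical thickness")


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    timeseries: dict[str, TimeSeriesSet]
    provenance: SimConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "age": s.age, "sex": s.sex}
            row.update({f"ct_{i + 1:02d}": v for i, v in enumerate(s.ct)})
            row["survival_months"] = s.survival_months
            row["event"] = s.event
            row["survival_class"] = s.survival_class
            rows.append(row)
        return pd.DataFrame(rows)


def class_of(survival_months: float) -> str:
    """Map a survival time to its class; 12 and 24 months fall in Y1TO2."""
    lo, hi = CLASS_BOUNDS
    if survival_months < lo:
        return "LT1Y"
    return "Y1TO2" if survival_months <= hi else "GT2Y"


def _group_sizes(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder rounding so sizes sum exactly to n."""
    raw = np.asarray(proportions, float) * n
    base = np.floor(raw).astype(int)
    remainder = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(remainder):
        base[order[i]] += 1
    return base.tolist()


def _truncated_lognormal(rng: np.random.Generator, scale: float, log_sd: float,
                         lo: float, hi: float) -> float:
    """Lognormal(median=scale) conditioned on the interval (lo, hi]."""
    dist = stats.lognorm(s=log_sd, scale=scale)
    a, b = dist.cdf(lo), dist.cdf(hi)
    if b - a < 1e-12:
        raise ConfigurationError(
            f"survival scale {scale} puts no mass in ({lo}, {hi}] months"
        )
    u = rng.uniform(a, b)
    return float(dist.ppf(u))


def generate_timeseries(record: SubjectRecord, config: SimConfig,
                        rng: np.random.Generator) -> TimeSeriesSet:
    """Simulate one subject's network-blocked BOLD matrix.

    Latent network signals are multivariate normal with covariance equal to
    the group's coupling matrix; each voxel is its network latent plus iid
    N(0, noise_sd^2) noise.
    """
    g = CLASSES.index(record.survival_class)
    C = config.coupling_matrices[g]
    # symmetric square root: stable even for coupling entries of exactly 1
    w, V = np.linalg.eigh(C)
    root = (V * np.sqrt(np.maximum(w, 0.0))) @ V.T
    latents = rng.standard_normal((config.n_frames, config.n_networks)) @ root
    blocks = {}
    shape = (config.n_frames, config.voxels_per_network)
    for i, net in enumerate(config.networks):
        if config.noise_sd > 0:
            voxels = latents[:, [i]] + config.noise_sd * rng.standard_normal(shape)
        else:
            voxels = np.broadcast_to(latents[:, [i]], shape).copy()
        blocks[net] = voxels
    return TimeSeriesSet(blocks=blocks)


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full cohort: demographics, thickness, survival, BOLD series.

    Identical configs (same seed) reproduce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _group_sizes(config.n_subjects, config.group_proportions)
    lo, hi = CLASS_BOUNDS
    intervals = [(0.0, lo - 1e-9), (lo, hi), (hi + 1e-9, MAX_SURVIVAL_MONTHS)]

    subjects: list[SubjectRecord] = []
    timeseries: dict[str, TimeSeriesSet] = {}
    sid = 0
    for g, (cls, size) in enumerate(zip(CLASSES, sizes)):
        for _ in range(size):
            subject_id = f"sub-{sid + 1:04d}"
            age = float(rng.normal(config.age_mean_by_group[g], config.age_sd))
            age = float(np.clip(age, 18.0, 95.0))
            sex = int(rng.random() < config.sex_prob_by_group[g])
            ct = np.asarray(config.ct_baseline) + config.ct_group_shift[g] \
                + config.ct_noise_sd * rng.standard_normal(34)
            ct = np.maximum(ct, 0.5)  # thickness stays physically positive
            t = _truncated_lognormal(
                rng, config.survival_scale_by_group[g], config.survival_log_sd,
                intervals[g][0], intervals[g][1],
            )
            event = int(rng.random() >= config.censor_rate)
            rec = SubjectRecord(
                subject_id=subject_id, age=age, sex=sex, ct=ct,
                survival_months=t, event=event, survival_class=cls,
            )
            subjects.append(rec)
            timeseries[subject_id] = generate_timeseries(rec, config, rng)
            sid += 1
    return Cohort(subjects=subjects, timeseries=timeseries, provenance=config)


def generate_probability_maps(config: SimConfig, grid_size: int | None = None,
                              rng: np.random.Generator | None = None) -> list[ProbabilityMap]:
    """Synthetic voxelwise network-membership maps on a shared grid.

    Stands in for published resting-state network probability maps: each
    network gets a contiguous high-probability segment (at least
    ``voxels_per_network`` strictly positive voxels, so top-k ROI selection
    is always well posed) plus a weak scattered tail elsewhere.
    """
    needed = config.n_networks * config.voxels_per_network
    if grid_size is None:
        grid_size = 2 * needed
    if grid_size < needed:
        raise ConfigurationError(
            f"grid of {grid_size} voxels cannot host {config.n_networks} maps "
            f"of {config.voxels_per_network} voxels"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    seg = grid_size // config.n_networks
    maps = []
    for i, net in enumerate(config.networks):
        values = np.zeros(grid_size)
        start = i * seg
        core = np.sort(rng.uniform(0.5, 1.0, config.voxels_per_network))[::-1]
        values[start: start + config.voxels_per_network] = core
        n_tail = max(grid_size // 50, 1)
        tail_idx = rng.choice(grid_size, size=n_tail, replace=False)
        values[tail_idx] = np.maximum(values[tail_idx], rng.uniform(0.01, 0.3, n_tail))
        maps.append(ProbabilityMap(network=net, values=values))
    return maps


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write cohort.csv plus one time-series CSV per subject; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = cohort.to_frame()
    cohort_path = out / "cohort.csv"
    table.to_csv(cohort_path, index=False)
    paths["cohort"] = str(cohort_path)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        cols = {}
        for net, block in ts.blocks.items():
            for j in range(block.shape[1]):
                cols[f"{net}:{j:03d}"] = block[:, j]
        p = ts_dir / f"{sid}.csv"
        pd.DataFrame(cols).to_csv(p, index=False, float_format="%.6f")
        paths[sid] = str(p)
    return paths


def save_probability_maps(maps: Sequence[ProbabilityMap], out_dir: str | Path) -> str:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.column_stack([m.values for m in maps])
    path = out / "probability_maps.csv"
    pd.DataFrame(arr, columns=[m.network for m in maps]).to_csv(path, index=False)
    sidecar = {"networks": [m.network for m in maps], "grid_size": int(arr.shape[0])}
    (out / "probability_maps.json").write_text(json.dumps(sidecar, indent=2))
    return str(path)


def load_probability_maps(path: str | Path) -> list[ProbabilityMap]:
    df = pd.read_csv(path)
    return [ProbabilityMap(network=c, values=df[c].to_numpy(float)) for c in df.columns]
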