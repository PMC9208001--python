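"""Synthetic cohorts with a planted hierarchical (rich/feeder/peripheral) connectome.

The generator emulates a resting-state case/control study with a paired
medication contrast: control subjects, patients scanned OFF medication and the
same patients scanned ON medication.  Each scan is a node x time matrix of
stationary Gaussian signals whose population correlation matrix carries

* a modular block structure (``n_modules`` contiguous modules),
* a planted rich club: ``richclub_size`` hub nodes, concentrated in the first
  half of the modules (the "core" modules), whose connections to the core tier
  receive ``hub_corr_bonus`` on top of the base correlations,
* a patient-OFF effect that attenuates every edge inside the core tier
  (rich and feeder nodes) by ``attenuation_delta`` and boosts
  peripheral-peripheral correlations by ``peripheral_boost_beta``,
* a patient-ON effect that restores a fraction ``restoration_rho`` of the
  attenuation and removes the peripheral boost.

Node tiers are planted deterministically: hub nodes are dealt round-robin to
the core modules; the remaining core-module nodes form the planted feeder
tier; nodes of the non-core modules form the planted peripheral tier.  The
hub bonus is restricted to hub <-> core-tier edges so that peripheral nodes
have no strong connection to any hub -- this is what makes the downstream
classification recover a nonempty peripheral class.

Timepoints are drawn i.i.d. from N(0, R + noise_sd^2 I); there is no temporal
autocorrelation because every downstream statistic consumes only the Pearson
correlation matrix.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TimeSeriesPanel",
    "GroundTruth",
    "build_target_covariance",
    "simulate_cohort",
    "write_cohort",
    "load_panel",
    "load_cohort_table",
]

ARMS = ("control", "off", "on")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions: 90 nodes, 230 timepoints, 30 controls
    and 30 paired patients, attenuation 0.3 with 80% restoration under
    medication and a 10% peripheral compensation boost.
    """

    n_nodes: int = 90
    n_timepoints: int = 230
    n_controls: int = 30
    n_patients: int = 30
    n_modules: int = 6
    richclub_size: int = 13
    base_within_module_corr: float = 0.30
    base_between_module_corr: float = 0.05
    hub_corr_bonus: float = 0.35
    attenuation_delta: float = 0.30
    restoration_rho: float = 0.80
    peripheral_boost_beta: float = 0.10
    noise_sd: float = 0.5
    age_mean: float = 60.0
    age_sd: float = 8.0
    sex_ratio: float = 0.5
    confound_age_shift: float = 0.0  # optional: add years to patients to test adjustment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if not 0 <= self.attenuation_delta < 1:
            raise ValueError("attenuation_delta must be in [0, 1)")
        if not 0 <= self.restoration_rho <= 1:
            raise ValueError("restoration_rho must be in [0, 1]")
        if self.peripheral_boost_beta < 0:
            raise ValueError("peripheral_boost_beta must be >= 0")
        if not 0 < self.richclub_size < self.n_nodes:
            raise ValueError("richclub_size must be in (0, n_nodes)")
        if not 1 <= self.n_modules <= self.n_nodes:
            raise ValueError("n_modules must be in [1, n_nodes]")
        for name in ("base_within_module_corr", "base_between_module_corr"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.hub_corr_bonus < 0:
            raise ValueError("hub_corr_bonus must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- planted layout ----------------------------------------------------

    def module_of(self) -> np.ndarray:
        """Module index of each node (contiguous, near-equal blocks)."""
        return np.repeat(
            np.arange(self.n_modules),
            np.diff(np.linspace(0, self.n_nodes, self.n_modules + 1).astype(int)),
        )

    def core_modules(self) -> np.ndarray:
        """Modules hosting the planted hubs (first half, at least one)."""
        return np.arange(max(1, self.n_modules // 2))

    def planted_tiers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rich, feeder, peripheral) node index arrays of the planted layout."""
        modules = self.module_of()
        core = self.core_modules()
        core_nodes = np.flatnonzero(np.isin(modules, core))
        if self.richclub_size > core_nodes.size:
            raise ValueError(
                "richclub_size exceeds the capacity of the core modules "
                f"({core_nodes.size} nodes)"
            )
        # deal hubs round-robin over core modules, lowest node index first
        per_module = [list(np.flatnonzero(modules == m)) for m in core]
        rich: list[int] = []
        i = 0
        while len(rich) < self.richclub_size:
            bucket = per_module[i % len(per_module)]
            if bucket:
                rich.append(bucket.pop(0))
            i += 1
        rich_arr = np.sort(np.asarray(rich, dtype=int))
        feeder = np.setdiff1d(core_nodes, rich_arr)
        peripheral = np.setdiff1d(np.arange(self.n_nodes), core_nodes)
        return rich_arr, feeder, peripheral


@dataclass
class TimeSeriesPanel:
    """Per-scan node x time matrices with shared node labels."""

    subject_ids: list[str]
    node_labels: list[str]
    data: dict[str, np.ndarray]  # scan id -> (n_nodes, n_timepoints)

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        for sid in self.subject_ids:
            ts = self.data[sid]
            if ts.shape[0] != n:
                raise ValueError(f"scan {sid}: node count {ts.shape[0]} != {n}")
            if ts.shape[1] < 3:
                raise ValueError(f"scan {sid}: fewer than 3 timepoints")


@dataclass
class GroundTruth:
    """Planted structure echoed back for validation."""

    rich_nodes: np.ndarray
    feeder_nodes: np.ndarray
    peripheral_nodes: np.ndarray
    target_correlation: dict[str, np.ndarray]  # arm -> matrix
    config: SimConfig = field(repr=False)


def _nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    if vals[0] >= 0:
        return mat
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2


def build_target_covariance(cfg: SimConfig, arm: str) -> np.ndarray:
    """Population correlation matrix of one study arm.

    Construction rules (applied to the off-diagonal entries, then the matrix
    is repaired to the nearest PSD correlation matrix by eigenvalue clipping):

    1. within-module pairs get ``base_within_module_corr``, between-module
       pairs ``base_between_module_corr``;
    2. hub <-> core-tier pairs (one endpoint a planted hub, the other a rich
       or feeder node) get ``hub_corr_bonus`` added;
    3. ``off`` arm: core-tier internal pairs (both endpoints rich or feeder)
       are multiplied by ``1 - attenuation_delta`` and peripheral-peripheral
       pairs by ``1 + peripheral_boost_beta``; ``on`` arm: core-tier pairs
       are multiplied by ``1 - attenuation_delta * (1 - restoration_rho)``
       and the peripheral boost is absent.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    modules = cfg.module_of()
    rich, feeder, peripheral = cfg.planted_tiers()
    n = cfg.n_nodes

    same_module = modules[:, None] == modules[None, :]
    R = np.where(same_module, cfg.base_within_module_corr, cfg.base_between_module_corr)

    is_rich = np.zeros(n, bool)
    is_rich[rich] = True
    is_core = np.zeros(n, bool)
    is_core[rich] = True
    is_core[feeder] = True
    is_peri = ~is_core

    hub_pair = (is_rich[:, None] & is_core[None, :]) | (is_core[:, None] & is_rich[None, :])
    R = R + np.where(hub_pair, cfg.hub_corr_bonus, 0.0)

    core_pair = is_core[:, None] & is_core[None, :]
    peri_pair = is_peri[:, None] & is_peri[None, :]
    if arm == "off":
        R = np.where(core_pair, R * (1 - cfg.attenuation_delta), R)
        R = np.where(peri_pair, R * (1 + cfg.peripheral_boost_beta), R)
    elif arm == "on":
        R = np.where(core_pair, R * (1 - cfg.attenuation_delta * (1 - cfg.restoration_rho)), R)

    np.fill_diagonal(R, 1.0)
    off_diag = R[~np.eye(n, dtype=bool)]
    if np.any(off_diag >= 1.0):
        raise ValueError("configuration produces off-diagonal correlations >= 1")
    return _nearest_psd_correlation(R)


def simulate_cohort(cfg: SimConfig) -> tuple[TimeSeriesPanel, pd.DataFrame, GroundTruth]:
    """Draw a full cohort: controls plus paired OFF/ON patient scans.

    Each scan's timepoints are i.i.d. multivariate normal with covariance
    ``R_arm + noise_sd^2 I``.  The same seed reproduces the cohort bitwise.
    Patient OFF and ON scans share age and sex through the pair id; the scans
    themselves are drawn independently.
    """
    rng = np.random.default_rng(cfg.seed)
    rich, feeder, peripheral = cfg.planted_tiers()
    targets = {arm: build_target_covariance(cfg, arm) for arm in ARMS}
    chol = {
        arm: np.linalg.cholesky(R + cfg.noise_sd**2 * np.eye(cfg.n_nodes) + 1e-10 * np.eye(cfg.n_nodes))
        for arm, R in targets.items()
    }

    node_labels = [f"node{i:03d}" for i in range(cfg.n_nodes)]
    rows = []
    data: dict[str, np.ndarray] = {}
    subject_ids: list[str] = []

    def draw(arm: str) -> np.ndarray:
        z = rng.standard_normal((cfg.n_timepoints, cfg.n_nodes))
        return np.ascontiguousarray((z @ chol[arm].T).T)

    for i in range(cfg.n_controls):
        sid = f"con{i:03d}"
        age = rng.normal(cfg.age_mean, cfg.age_sd)
        sex = int(rng.random() < cfg.sex_ratio)
        fd = rng.lognormal(mean=np.log(0.15), sigma=0.4)
        data[sid] = draw("control")
        subject_ids.append(sid)
        rows.append((sid, "control", "none", "", age, sex, fd))

    for i in range(cfg.n_patients):
        pair = f"pat{i:03d}"
        age = rng.normal(cfg.age_mean, cfg.age_sd) + cfg.confound_age_shift
        sex = int(rng.random() < cfg.sex_ratio)
        for cond in ("off", "on"):
            sid = f"{pair}_{cond}"
            fd = rng.lognormal(mean=np.log(0.15), sigma=0.4)
            data[sid] = draw(cond)
            subject_ids.append(sid)
            rows.append((sid, "patient", cond, pair, age, sex, fd))

    cohort = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "condition", "pair_id", "age", "sex", "mean_fd"],
    )
    panel = TimeSeriesPanel(subject_ids, node_labels, data)
    truth = GroundTruth(rich, feeder, peripheral, targets, cfg)
    return panel, cohort, truth


# -- on-disk format --------------------------------------------------------


def write_cohort(
    panel: TimeSeriesPanel, cohort: pd.DataFrame, truth: GroundTruth, outdir: str | Path
) -> None:
    """Write one TSV per scan (rows = nodes), the cohort CSV and ground truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid in panel.subject_ids:
        np.savetxt(outdir / f"{sid}.tsv", panel.data[sid], delimiter="\t", fmt="%.8g")
    cohort.to_csv(outdir / "cohort.csv", index=False)
    gt = {
        "rich_nodes": truth.rich_nodes.tolist(),
        "feeder_nodes": truth.feeder_nodes.tolist(),
        "peripheral_nodes": truth.peripheral_nodes.tolist(),
        "config": dataclasses.asdict(truth.config),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))


def load_panel(indir: str | Path, cohort: pd.DataFrame) -> TimeSeriesPanel:
    indir = Path(indir)
    data = {}
    node_labels: list[str] | None = None
    for sid in cohort["subject_id"]:
        ts = np.loadtxt(indir / f"{sid}.tsv", delimiter="\t")
        data[sid] = np.atleast_2d(ts)
        if node_labels is None:
            node_labels = [f"node{i:03d}" for i in range(data[sid].shape[0])]
    if node_labels is None:
        raise ValueError("cohort table lists no subjects")
    return TimeSeriesPanel(list(cohort["subject_id"]), node_labels, data)


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, dtype={"pair_id": str}, keep_default_na=False)
    required = {"subject_id", "group", "condition", "age", "sex"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad = ~cohort["group"].isin(["control", "patient"])
    if bad.any():
        raise ValueError("group must be 'control' or 'patient'")
    return cohort
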