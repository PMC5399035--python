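"""Synthetic MEG cohorts from phase-coupled alpha oscillators.

The generator produces sensor-level magnetometer recordings whose
source-space phase-coupling structure is known by construction, so every
downstream stage (filtering, beamforming, PLV, group statistics) can be
validated without real recordings.

Coupling model.  Source phases are taken from a correlated circular
complex Gaussian field: innovations ε(t) ~ CN(0, Ρ) are AR(1)-smoothed in
time (coherence time τ) and the phase of source k is
2π·f_c·t + arg z_k(t).  For a circular Gaussian pair with correlation ρ
the phase-difference resultant has the closed form

    PLV(ρ) = (π/4)·ρ·₂F₁(1/2, 1/2; 2; ρ²)

which is strictly increasing from 0 to 1, so any target PLV matrix maps
elementwise to a Gaussian correlation matrix; the target is feasible
exactly when that matrix is positive semidefinite.

Cohort defaults mirror the population this pipeline is aimed at:
three groups (HC/SCD/MCI, 39/41/51 subjects), 4 s epochs at 1 kHz,
group ages 70.4±3.7 / 71.6±4.5 / 73.0±3.7 years, and a connectivity
phenotype of anterior hyper-synchronisation plus posterior
hypo-synchronisation in SCD and MCI relative to HC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import hyp2f1

from .forward import leadfield_matrix
from .preprocessing import SensorEpochs

GROUPS = ("HC", "SCD", "MCI")

#: phase-coherence time of the oscillators, seconds (sets the phase-noise
#: bandwidth, ~1/(πτ) ≈ 6 Hz around the carrier)
DEFAULT_COHERENCE_TAU = 0.05
#: carrier frequency: the sample-average alpha peak the band is anchored to
DEFAULT_CENTER_FREQ = 9.4


class InfeasibleCouplingError(ValueError):
    """Requested PLV matrix cannot be realised by any Gaussian field."""


# ---------------------------------------------------------------------------
# PLV <-> Gaussian correlation map

_RHO_GRID = np.linspace(0.0, 1.0, 4001)
_PLV_GRID = np.pi / 4.0 * _RHO_GRID * hyp2f1(0.5, 0.5, 2.0, _RHO_GRID**2)


def plv_from_rho(rho):
    """Expected PLV of a circular complex Gaussian pair with correlation ρ."""
    rho = np.asarray(rho, float)
    return np.pi / 4.0 * rho * hyp2f1(0.5, 0.5, 2.0, rho**2)


def rho_from_plv(plv):
    """Inverse of :func:`plv_from_rho` (monotone; tabulated inversion)."""
    return np.interp(np.asarray(plv, float), _PLV_GRID, _RHO_GRID)


# ---------------------------------------------------------------------------
# signal-level generators

def _coupling_factor(target_plv: np.ndarray) -> np.ndarray:
    """Factor L with LLᴴ = Ρ for the Gaussian correlation matrix implied by
    the PLV targets; raises with the offending pair if infeasible."""
    t = np.asarray(target_plv, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("target_plv must be square")
    if not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("target_plv must be symmetric")
    off = t - np.diag(np.diag(t))
    if off.min() < 0 or off.max() > 1:
        i, j = np.unravel_index(np.argmax(np.abs(off - 0.5)), t.shape)
        raise InfeasibleCouplingError(
            f"target PLV for pair ({i}, {j}) = {t[i, j]:.3f} outside [0, 1]")
    rho = rho_from_plv(t)
    np.fill_diagonal(rho, 1.0)
    vals, vecs = np.linalg.eigh(rho)
    if vals.min() < -1e-8:
        offdiag = rho - np.eye(len(rho))
        i, j = np.unravel_index(np.argmax(np.abs(offdiag)), rho.shape)
        raise InfeasibleCouplingError(
            f"implied correlation matrix is not positive semidefinite "
            f"(min eigenvalue {vals.min():.3e}); strongest requested pair "
            f"({i}, {j}) with PLV {t[i, j]:.3f} is the likely offender")
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_coupled_phases(n_sources: int, target_plv: np.ndarray,
                            n_samples: int, center_freq: float,
                            rate: float = 1000.0, seed: int = 0,
                            coherence_tau: float = DEFAULT_COHERENCE_TAU
                            ) -> np.ndarray:
    """Instantaneous phases (n_sources × n_samples) whose pairwise PLV
    converges to ``target_plv``; phases advance on average at
    ``center_freq`` Hz."""
    t = np.asarray(target_plv, float)
    if t.shape != (n_sources, n_sources):
        raise ValueError("target_plv must be n_sources × n_sources")
    L = _coupling_factor(t)
    rng = np.random.default_rng(seed)
    tau_samples = max(coherence_tau * rate, 1.0)
    a = np.exp(-1.0 / tau_samples)
    burn = int(10 * tau_samples)
    total = n_samples + burn
    eps = (rng.standard_normal((n_sources, total))
           + 1j * rng.standard_normal((n_sources, total))) / np.sqrt(2.0)
    z = lfilter([np.sqrt(1.0 - a**2)], [1.0, -a], L @ eps, axis=1)[:, burn:]
    ramp = 2.0 * np.pi * center_freq * np.arange(n_samples) / rate
    phase = np.angle(z) + ramp
    return np.angle(np.exp(1j * phase))  # wrap to (−π, π]


def phases_to_source_signals(phases: np.ndarray, amplitude: float = 1.0,
                             amplitude_sd: float = 0.0, noise_sd: float = 0.0,
                             seed: int = 0, rate: float = 1000.0,
                             envelope_tau: float = 0.1) -> np.ndarray:
    """Oscillatory source series: (Rician) envelope × cos(phase) + noise.

    With ``amplitude_sd`` = 0 the envelope is the constant ``amplitude``
    and zero noise makes the output a deterministic function of the
    phases.  With ``amplitude_sd`` > 0 the envelope is
    |amplitude + c(t)| for a smoothed complex Gaussian c with per-component
    sd ``amplitude_sd``, so the mean signal power is
    (amplitude² + 2·amplitude_sd²)/2.
    """
    if amplitude_sd < 0 or noise_sd < 0:
        raise ValueError("amplitude_sd and noise_sd must be non-negative")
    phases = np.asarray(phases, float)
    rng = np.random.default_rng(seed)
    if amplitude_sd > 0:
        tau_samples = max(envelope_tau * rate, 1.0)
        a = np.exp(-1.0 / tau_samples)
        burn = int(10 * tau_samples)
        shape = phases.shape[:-1] + (phases.shape[-1] + burn,)
        c = (rng.standard_normal(shape)
             + 1j * rng.standard_normal(shape)) * amplitude_sd
        c = lfilter([np.sqrt(1.0 - a**2)], [1.0, -a], c, axis=-1)[..., burn:]
        envelope = np.abs(amplitude + c)
    else:
        envelope = amplitude
    out = envelope * np.cos(phases)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=phases.shape)
    return out


def forward_project_sphere(source_signals: np.ndarray,
                           source_positions: np.ndarray,
                           source_orientations: np.ndarray,
                           sensor_positions: np.ndarray,
                           sensor_orientations: np.ndarray,
                           sphere_center: np.ndarray | None = None
                           ) -> np.ndarray:
    """Project source series to magnetometer sensors through the
    single-sphere forward model; output is channels × samples."""
    ori = np.asarray(source_orientations, float)
    norms = np.linalg.norm(ori, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("source orientations must be unit norm")
    lf = leadfield_matrix(source_positions, sensor_positions,
                          sensor_orientations, source_orientations=ori,
                          center=sphere_center)
    return lf @ np.asarray(source_signals, float)


# ---------------------------------------------------------------------------
# toy geometry and atlas

@dataclass(frozen=True)
class SphereAtlas:
    """Point → area map: each area is a ball around a centroid; points
    outside every ball are unlabelled (returns None)."""

    names: tuple[str, ...]
    centers: np.ndarray
    radius: float

    def __len__(self) -> int:
        return len(self.names)

    def label(self, point: np.ndarray) -> str | None:
        d = np.linalg.norm(self.centers - np.asarray(point, float), axis=1)
        i = int(np.argmin(d))
        return self.names[i] if d[i] <= self.radius else None


ANTERIOR_AREAS = ("FP-L", "FP-R", "SF-L", "SF-R")
POSTERIOR_AREAS = ("SP-L", "SP-R", "LO-L", "LO-R", "PC", "CU")
TOY_AREAS = ANTERIOR_AREAS + POSTERIOR_AREAS

#: toy resting-state networks over the synthetic atlas
TOY_RSNS = {
    "DAN": ("SF-L", "SF-R", "SP-L", "SP-R"),
    "aDMN": ("FP-L", "FP-R"),
    "pDMN": ("PC", "CU"),
}


def _fibonacci_cap(n: int, radius: float, z_min: float) -> np.ndarray:
    """Roughly uniform points on the spherical cap z/r ≥ z_min."""
    i = np.arange(n) + 0.5
    z = z_min + (1.0 - z_min) * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z**2)
    return radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def toy_geometry(n_sensors: int = 80, n_sources_per_area: int = 3,
                 sensor_radius: float = 0.12, head_radius: float = 0.08,
                 area_radius: float = 0.02, seed: int = 12345):
    """Desk-scale head: magnetometers on a spherical cap, 10 atlas areas
    (4 anterior, 6 posterior) spread quasi-uniformly over the upper cortex
    shell, a few tangential sources per area.

    Returns (sensor_positions, sensor_orientations, source_positions,
    source_orientations, atlas_labels, atlas).  The 4 most anterior
    centroids (largest y) carry the anterior area names, matching the
    posterior-channel convention used for alpha-peak detection.
    """
    sensors = _fibonacci_cap(n_sensors, sensor_radius, z_min=0.05)
    sensor_ori = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)

    # quasi-uniform centroids, most-anterior first so names line up
    dirs = _fibonacci_cap(len(TOY_AREAS), 1.0, z_min=0.25)
    dirs = dirs[np.argsort(-dirs[:, 1])]
    centers = head_radius * dirs
    atlas = SphereAtlas(TOY_AREAS, centers, area_radius)

    rng = np.random.default_rng(seed)
    positions, labels = [], []
    for name, c in zip(TOY_AREAS, centers):
        for _ in range(n_sources_per_area):
            offset = rng.normal(scale=area_radius / 3.0, size=3)
            r_off = np.linalg.norm(offset)
            if r_off > 0.75 * area_radius:  # keep sources inside their area
                offset *= 0.75 * area_radius / r_off
            p = c + offset
            p *= min(1.0, 0.95 * head_radius / np.linalg.norm(p))
            positions.append(p)
            labels.append(name)
    positions = np.array(positions)

    # tangential orientations (radial dipoles are magnetically silent)
    radial = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    ref = np.where(np.abs(radial[:, 2:3]) < 0.9,
                   np.tile([0.0, 0.0, 1.0], (len(radial), 1)),
                   np.tile([1.0, 0.0, 0.0], (len(radial), 1)))
    tang = np.cross(radial, ref)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return sensors, sensor_ori, positions, tang, np.array(labels, object), atlas


# ---------------------------------------------------------------------------
# cohort specification

@dataclass
class ScoreModel:
    """Linear map from selected ground-truth edge PLVs to a score.

    score = intercept(group) + Σ_e weight_e · (PLV_e − base_e) + N(0, sd²)
    """

    intercepts: dict[str, float]
    edge_weights: dict[tuple[str, str], float]
    noise_sd: float


@dataclass
class GroundTruthSpec:
    """Everything the cohort generator needs, with the realised connectivity
    ground truth derivable from ``base_plv`` + ``group_effects``."""

    n_subjects_per_group: dict[str, int]
    source_positions: np.ndarray
    source_orientations: np.ndarray
    atlas_labels: np.ndarray
    sensor_positions: np.ndarray
    sensor_orientations: np.ndarray
    base_plv: np.ndarray                 # area × area, unit diagonal
    area_names: list[str]
    group_effects: list[tuple[tuple[str, str], str, float]]
    age_distribution: dict[str, tuple[float, float]]
    score_models: dict[str, ScoreModel]
    seed: int
    rate: float = 1000.0
    epoch_seconds: float = 4.0
    n_epochs_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (47.6, 7.3), "SCD": (46.2, 9.4),
                                 "MCI": (42.2, 7.0)})
    min_epochs: int = 15
    center_freq: float = DEFAULT_CENTER_FREQ
    within_area_plv: float = 0.45
    coherence_tau: float = DEFAULT_COHERENCE_TAU
    amplitude: float = 1.0
    amplitude_sd: float = 0.3
    noise_sd: float = 0.5
    sensor_noise_factor: float = 0.1

    def __post_init__(self) -> None:
        self.base_plv = np.asarray(self.base_plv, float)
        n = len(self.area_names)
        if self.base_plv.shape != (n, n):
            raise ValueError("base_plv must be area × area")
        if not np.allclose(self.base_plv, self.base_plv.T):
            raise ValueError("base_plv must be symmetric")
        if not np.allclose(np.diag(self.base_plv), 1.0):
            raise ValueError("base_plv must have unit diagonal")
        if n < 2:
            raise ValueError("need at least 2 atlas areas")
        for (pair, group, delta) in self.group_effects:
            tgt = self.edge_target(pair, group)
            if not 0.0 <= tgt <= 1.0:
                raise ValueError(
                    f"effect {pair}/{group} drives target PLV to {tgt:.3f}, "
                    "outside [0, 1]")

    def edge_target(self, pair: tuple[str, str], group: str) -> float:
        """Target PLV of an area pair for a group (base + summed deltas)."""
        i, j = (self.area_names.index(pair[0]), self.area_names.index(pair[1]))
        val = self.base_plv[i, j]
        for (p, g, d) in self.group_effects:
            if g == group and set(p) == {pair[0], pair[1]}:
                val += d
        return float(val)

    def group_target_matrix(self, group: str) -> np.ndarray:
        """Area-level target PLV matrix for one group."""
        m = self.base_plv.copy()
        for (pair, g, d) in self.group_effects:
            if g != group:
                continue
            i, j = (self.area_names.index(pair[0]),
                    self.area_names.index(pair[1]))
            m[i, j] += d
            m[j, i] += d
        return m

    def source_target_matrix(self, group: str) -> np.ndarray:
        """Source-level target PLV matrix (within-area pairs at
        ``within_area_plv``, cross-area pairs at the area target)."""
        area_m = self.group_target_matrix(group)
        idx = np.array([self.area_names.index(a) for a in self.atlas_labels])
        m = area_m[np.ix_(idx, idx)].copy()
        same = idx[:, None] == idx[None, :]
        m[same] = self.within_area_plv
        np.fill_diagonal(m, 1.0)
        return m


@dataclass
class SubjectRecord:
    """One synthetic participant."""

    subject_id: str
    group: str
    age: float
    scores: dict[str, float]
    hippocampal_volume: float
    sensor_epochs: SensorEpochs
    n_epochs: int = 0
    true_edge_plv: dict[tuple[str, str], float] = field(default_factory=dict)


# the two edges the synthetic neuropsychological scores load on: one
# anterior hyper-synchronising edge (negative weight: more anterior
# synchronisation, worse score) and one posterior hypo-synchronising edge
# (positive weight)
SCORE_EDGE_ANT = ("FP-L", "FP-R")
SCORE_EDGE_POST = ("CU", "PC")

DEFAULT_HYPER_EDGES = (("FP-L", "FP-R"), ("FP-L", "SF-L"), ("FP-R", "SF-R"))
DEFAULT_HYPO_EDGES = tuple(
    (a, b)
    for i, a in enumerate(POSTERIOR_AREAS) for b in POSTERIOR_AREAS[i + 1:]
    if {a, b} != {"LO-L", "LO-R"})  # 14 of the 15 posterior pairs


def default_group_effects(hyper_delta: tuple[float, float] = (0.12, 0.15),
                          hypo_delta: tuple[float, float] = (-0.10, -0.12)
                          ) -> list[tuple[tuple[str, str], str, float]]:
    """Anterior-hyper / posterior-hypo phenotype for SCD and MCI: 3 edges
    up, 14 edges down, with MCI slightly beyond SCD."""
    effects = []
    for pair in DEFAULT_HYPER_EDGES:
        effects.append((pair, "SCD", hyper_delta[0]))
        effects.append((pair, "MCI", hyper_delta[1]))
    for pair in DEFAULT_HYPO_EDGES:
        effects.append((pair, "SCD", hypo_delta[0]))
        effects.append((pair, "MCI", hypo_delta[1]))
    return effects


def default_spec(n_subjects_per_group: dict[str, int] | None = None,
                 rate: float = 1000.0, epoch_seconds: float = 4.0,
                 n_epochs_mean: float | None = None, seed: int = 0,
                 group_effects: list | None = None,
                 n_sensors: int = 80, n_sources_per_area: int = 3,
                 within_network_plv: float = 0.25,
                 background_plv: float = 0.10) -> GroundTruthSpec:
    """Study-emulating cohort specification on the toy head.

    Defaults: 39/41/51 subjects (HC/SCD/MCI), 4 s epochs at 1 kHz with
    group-wise epoch counts matching typical clean-epoch yields, alpha
    carrier at 9.4 Hz, and the anterior-hyper / posterior-hypo effect
    geometry.  Baseline coupling is block-structured: pairs within the
    anterior or within the posterior set couple at ``within_network_plv``,
    long-range anterior–posterior pairs at ``background_plv``.
    ``n_epochs_mean`` overrides the per-group epoch-count distribution with
    a common mean (sd 0) for desk-scale runs.
    """
    if n_subjects_per_group is None:
        n_subjects_per_group = {"HC": 39, "SCD": 41, "MCI": 51}
    sens_p, sens_o, src_p, src_o, labels, _atlas = toy_geometry(
        n_sensors=n_sensors, n_sources_per_area=n_sources_per_area)
    n_areas = len(TOY_AREAS)
    base = np.full((n_areas, n_areas), background_plv)
    for block in (ANTERIOR_AREAS, POSTERIOR_AREAS):
        for a in block:
            for b in block:
                i, j = TOY_AREAS.index(a), TOY_AREAS.index(b)
                base[i, j] = within_network_plv
    np.fill_diagonal(base, 1.0)
    if group_effects is None:
        group_effects = default_group_effects()
    score_models = {
        "MMSE": ScoreModel(
            intercepts={"HC": 29.0, "SCD": 29.0, "MCI": 29.0},
            edge_weights={SCORE_EDGE_ANT: -8.0, SCORE_EDGE_POST: 10.0},
            noise_sd=1.0),
        "BNT": ScoreModel(
            intercepts={"HC": 53.0, "SCD": 53.0, "MCI": 53.0},
            edge_weights={SCORE_EDGE_ANT: -20.0, SCORE_EDGE_POST: 25.0},
            noise_sd=6.0),
    }
    spec = GroundTruthSpec(
        n_subjects_per_group=n_subjects_per_group,
        source_positions=src_p, source_orientations=src_o,
        atlas_labels=labels,
        sensor_positions=sens_p, sensor_orientations=sens_o,
        base_plv=base, area_names=list(TOY_AREAS),
        group_effects=group_effects,
        age_distribution={"HC": (70.4, 3.7), "SCD": (71.6, 4.5),
                          "MCI": (73.0, 3.7)},
        score_models=score_models,
        seed=seed, rate=rate, epoch_seconds=epoch_seconds)
    if n_epochs_mean is not None:
        spec.n_epochs_distribution = {g: (float(n_epochs_mean), 0.0)
                                      for g in GROUPS}
    return spec


# hippocampal volume (normalised by intracranial volume): MCI below HC/SCD,
# with a weak positive loading on posterior connectivity
HIPPOCAMPAL_MODEL = ScoreModel(
    intercepts={"HC": 5.0e-3, "SCD": 5.0e-3, "MCI": 4.4e-3},
    edge_weights={SCORE_EDGE_POST: 2.0e-3},
    noise_sd=0.5e-3)


def _edge_plv_from_phases(phases: np.ndarray, labels: np.ndarray,
                          pair: tuple[str, str], n_epochs: int) -> float:
    """Realised truth-level PLV of one area pair from the generated phases
    (segment-wise resultants, averaged per the estimator's convention)."""
    ia = np.flatnonzero(labels == pair[0])
    ib = np.flatnonzero(labels == pair[1])
    seg = np.array_split(np.arange(phases.shape[1]), n_epochs)
    vals = []
    for s in seg:
        z = np.exp(1j * phases[:, s])
        r = np.abs(z[ia] @ z[ib].conj().T) / len(s)
        vals.append(r.mean())
    return float(np.mean(vals))


def generate_edge_cohort(spec: GroundTruthSpec):
    """Connectivity-level cohort: per-subject area-edge PLV plus covariates,
    skipping forward projection and reconstruction.

    Each subject's edge values are the segment-averaged, cross-pair-averaged
    resultants of their generated source phases — the same estimator the
    full pipeline applies after inversion — so the subject-to-subject
    variability is the finite-sampling noise of the PLV estimate itself.
    Returns (covariates DataFrame, values [subjects × edges], edge names).
    Deterministic given ``spec.seed``; the covariate stream matches
    :func:`generate_cohort`'s models.
    """
    import pandas as pd

    from .connectivity import PhaseSeries, plv_area

    ss = np.random.SeedSequence(spec.seed)
    labels = np.asarray(spec.atlas_labels)
    n_sources = len(labels)
    samples_per_epoch = int(round(spec.epoch_seconds * spec.rate))
    base_by_edge = {}
    rows, values = [], []
    edge_names = None
    for group in GROUPS:
        n_subj = spec.n_subjects_per_group.get(group, 0)
        if n_subj == 0:
            continue
        target = spec.source_target_matrix(group)
        mu_age, sd_age = spec.age_distribution[group]
        mu_ep, sd_ep = spec.n_epochs_distribution[group]
        for _ in range(n_subj):
            child = ss.spawn(1)[0]
            seeds = child.generate_state(5) % (2**31)
            rng = np.random.default_rng(child)
            n_epochs = max(spec.min_epochs,
                           int(round(rng.normal(mu_ep, sd_ep))))
            phases = simulate_coupled_phases(
                n_sources, target, n_epochs * samples_per_epoch,
                spec.center_freq, rate=spec.rate, seed=int(seeds[0]),
                coherence_tau=spec.coherence_tau)
            ph = phases.reshape(n_sources, n_epochs,
                                samples_per_epoch).transpose(1, 0, 2)
            conn = plv_area(PhaseSeries(ph), labels)
            if edge_names is None:
                edge_names = [f"{a}|{b}"
                              for i, a in enumerate(conn.area_names)
                              for b in conn.area_names[i + 1:]]
                for i, a in enumerate(conn.area_names):
                    for b in conn.area_names[i + 1:]:
                        ia = spec.area_names.index(a)
                        ib = spec.area_names.index(b)
                        base_by_edge[(a, b)] = spec.base_plv[ia, ib]
            iu = np.triu_indices(len(conn.area_names), k=1)
            values.append(conn.plv[iu])
            age = float(rng.normal(mu_age, sd_age))
            row = {"subject_id": f"S{len(rows) + 1:03d}", "group": group,
                   "age": age, "n_epochs": n_epochs}
            edge_lookup = {pair: conn.edge(*pair) for pair in base_by_edge}
            for name, model in spec.score_models.items():
                val = model.intercepts[group]
                for e, w in model.edge_weights.items():
                    key = tuple(sorted(e))
                    val += w * (edge_lookup[key] - base_by_edge[key])
                row[name] = float(val + rng.normal(0.0, model.noise_sd))
            vol = HIPPOCAMPAL_MODEL.intercepts[group]
            for e, w in HIPPOCAMPAL_MODEL.edge_weights.items():
                key = tuple(sorted(e))
                vol += w * (edge_lookup[key] - base_by_edge[key])
            row["hippocampal_volume"] = float(
                vol + rng.normal(0.0, HIPPOCAMPAL_MODEL.noise_sd))
            rows.append(row)
    return pd.DataFrame(rows), np.asarray(values), edge_names


def generate_cohort(spec: GroundTruthSpec
                    ) -> tuple[list[SubjectRecord], dict]:
    """Generate the full cohort plus a ground-truth report.

    Deterministic given ``spec.seed``.  The report records the per-group
    area-level target PLV matrices, the effect list, and each subject's
    realised truth-level PLV on the score-model edges.
    """
    ss = np.random.SeedSequence(spec.seed)
    labels = np.asarray(spec.atlas_labels)
    n_sources = len(labels)
    samples_per_epoch = int(round(spec.epoch_seconds * spec.rate))
    lf = leadfield_matrix(spec.source_positions, spec.sensor_positions,
                          spec.sensor_orientations,
                          source_orientations=spec.source_orientations)

    score_edges = sorted({e for m in spec.score_models.values()
                          for e in m.edge_weights}
                         | set(HIPPOCAMPAL_MODEL.edge_weights))
    base_by_edge = {e: spec.base_plv[spec.area_names.index(e[0]),
                                     spec.area_names.index(e[1])]
                    for e in score_edges}

    subjects: list[SubjectRecord] = []
    report = {
        "seed": spec.seed,
        "group_effects": [
            {"edge": list(pair), "group": g, "delta": d}
            for (pair, g, d) in spec.group_effects],
        "group_target_plv": {
            g: spec.group_target_matrix(g).tolist() for g in GROUPS
            if g in spec.n_subjects_per_group},
        "area_names": list(spec.area_names),
        "subjects": [],
    }

    counter = 0
    for group in GROUPS:
        n_subj = spec.n_subjects_per_group.get(group, 0)
        if n_subj == 0:
            continue
        target = spec.source_target_matrix(group)
        mu_age, sd_age = spec.age_distribution[group]
        mu_ep, sd_ep = spec.n_epochs_distribution[group]
        for _ in range(n_subj):
            child = ss.spawn(1)[0]
            seeds = child.generate_state(5) % (2**31)
            rng = np.random.default_rng(child)
            counter += 1
            sid = f"S{counter:03d}"

            n_epochs = max(spec.min_epochs,
                           int(round(rng.normal(mu_ep, sd_ep))))
            n_samples = n_epochs * samples_per_epoch
            phases = simulate_coupled_phases(
                n_sources, target, n_samples, spec.center_freq,
                rate=spec.rate, seed=int(seeds[0]),
                coherence_tau=spec.coherence_tau)
            signals = phases_to_source_signals(
                phases, amplitude=spec.amplitude,
                amplitude_sd=spec.amplitude_sd, noise_sd=spec.noise_sd,
                seed=int(seeds[1]), rate=spec.rate)
            sensor = lf @ signals
            if spec.sensor_noise_factor > 0:
                rms = np.sqrt(np.mean(sensor**2))
                sensor = sensor + rng.normal(
                    0.0, spec.sensor_noise_factor * rms, size=sensor.shape)
            data = sensor.reshape(sensor.shape[0], n_epochs,
                                  samples_per_epoch).transpose(1, 0, 2)
            epochs = SensorEpochs(data, spec.rate, spec.sensor_positions,
                                  spec.sensor_orientations)

            true_plv = {e: _edge_plv_from_phases(phases, labels, e, n_epochs)
                        for e in score_edges}
            age = float(rng.normal(mu_age, sd_age))
            scores = {}
            for name, model in spec.score_models.items():
                val = model.intercepts[group]
                for e, w in model.edge_weights.items():
                    val += w * (true_plv[e] - base_by_edge[e])
                scores[name] = float(val + rng.normal(0.0, model.noise_sd))
            vol = HIPPOCAMPAL_MODEL.intercepts[group]
            for e, w in HIPPOCAMPAL_MODEL.edge_weights.items():
                vol += w * (true_plv[e] - base_by_edge[e])
            vol = float(vol + rng.normal(0.0, HIPPOCAMPAL_MODEL.noise_sd))

            subjects.append(SubjectRecord(
                subject_id=sid, group=group, age=age, scores=scores,
                hippocampal_volume=vol, sensor_epochs=epochs,
                n_epochs=n_epochs, true_edge_plv=true_plv))
            report["subjects"].append({
                "subject_id": sid, "group": group, "age": age,
                "n_epochs": n_epochs,
                "true_edge_plv": {f"{a}|{b}": v
                                  for (a, b), v in true_plv.items()}})
    return subjects, report
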