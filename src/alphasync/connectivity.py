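"""Phase-locking-value (PLV) connectivity.

For two signals k, l with instantaneous phases φ_k(t), φ_l(t) the PLV of
one segment of T samples is

    PLV_kl = | (1/T) Σ_t exp(−j(φ_k(t) − φ_l(t))) |

i.e. the resultant length of the phase-difference phasors: 1 for perfect
locking, ~T^{-1/2} for independent phases.  Area-level connectivity
averages the per-source-pair PLV magnitudes over all cross-area pairs

    PLV_AB = (1/(N_A N_B)) Σ_{k∈A} Σ_{l∈B} PLV_kl

and a subject's value is the arithmetic mean over their segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

HILBERT_PAD_SAMPLES = 2000


class UndefinedPhaseError(ValueError):
    """Phase of a (near-)constant signal is undefined."""


@dataclass
class PhaseSeries:
    """Instantaneous phases, (n_epochs, n_sources, T), radians in (−π, π]."""

    phase: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, float)
        if self.phase.ndim == 2:
            self.phase = self.phase[np.newaxis]
        if self.phase.ndim != 3 or self.phase.shape[-1] < 1:
            raise ValueError("phase must be (epochs, sources, T) with T > 0")

    @property
    def n_epochs(self) -> int:
        return self.phase.shape[0]

    @property
    def n_sources(self) -> int:
        return self.phase.shape[1]

    @property
    def T(self) -> int:
        """Samples per segment."""
        return self.phase.shape[2]


@dataclass
class AreaConnectivity:
    """Symmetric area × area PLV matrix with bookkeeping."""

    plv: np.ndarray
    area_names: list[str]
    n_sources_per_area: dict[str, int] = field(default_factory=dict)
    n_epochs_used: int = 0

    def __post_init__(self) -> None:
        self.plv = np.asarray(self.plv, float)
        n = len(self.area_names)
        if self.plv.shape != (n, n):
            raise ValueError("plv shape must match area_names")
        if not np.allclose(self.plv, self.plv.T, atol=1e-12):
            raise ValueError("plv must be symmetric")
        off = self.plv[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("PLV entries must lie in [0, 1]")

    def edge(self, a: str, b: str) -> float:
        i, j = self.area_names.index(a), self.area_names.index(b)
        return float(self.plv[i, j])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form upper-triangle edge list (area_a, area_b, plv)."""
        rows = []
        n = len(self.area_names)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"area_a": self.area_names[i],
                             "area_b": self.area_names[j],
                             "plv": self.plv[i, j]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RSNDefinition:
    """Resting-state network membership (e.g. DAN, aDMN, pDMN) as area names."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"network {self.name} needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in network {self.name}")


def hilbert_phase(source_epochs: np.ndarray,
                  pad_samples: int = HILBERT_PAD_SAMPLES) -> PhaseSeries:
    """Instantaneous phase via the Hilbert analytic signal.

    Each epoch/source trace is reflection-padded by ``pad_samples`` per side
    before the transform (edge suppression), the padding removed after.
    """
    x = np.asarray(source_epochs, float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[np.newaxis]
    if x.shape[-1] <= 2:
        raise ValueError("epoch too short for phase estimation")
    rng_amp = np.ptp(x, axis=-1)
    if np.any(rng_amp == 0):
        e, s = np.argwhere(rng_amp == 0)[0]
        raise UndefinedPhaseError(
            f"constant signal (epoch {e}, source {s}) has no defined phase")
    pad = min(pad_samples, x.shape[-1] - 1)
    if pad > 0:
        xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    else:
        xp = x
    analytic = signal.hilbert(xp, axis=-1)
    phase = np.angle(analytic[..., pad:pad + x.shape[-1]])
    return PhaseSeries(phase if not squeeze else phase[0][np.newaxis])


def plv_pair(phase_k: np.ndarray, phase_l: np.ndarray) -> float:
    """Segment-averaged PLV between two phase traces.

    Inputs are (T,) single segments or (n_epochs, T); the per-segment
    resultant lengths are averaged over segments.
    """
    pk = np.atleast_2d(np.asarray(phase_k, float))
    pl = np.atleast_2d(np.asarray(phase_l, float))
    if pk.shape != pl.shape:
        raise ValueError("phase arrays must have identical shape")
    res = np.abs(np.exp(-1j * (pk - pl)).mean(axis=-1))
    return float(res.mean())


def _pairwise_plv_matrix(phase: np.ndarray) -> np.ndarray:
    """All-pairs segment-averaged PLV, phase (epochs, sources, T)."""
    n_ep, n_src, T = phase.shape
    acc = np.zeros((n_src, n_src))
    for e in range(n_ep):
        z = np.exp(1j * phase[e])
        acc += np.abs(z @ z.conj().T) / T
    acc /= n_ep
    np.fill_diagonal(acc, 1.0)
    return np.clip(acc, 0.0, 1.0)


def plv_area(phase: PhaseSeries, labels: list[str] | np.ndarray) -> AreaConnectivity:
    """Area-averaged PLV: mean of per-source-pair PLV magnitudes over all
    cross-area source pairs (within-area diagonal fixed at 1)."""
    labels = np.asarray(labels)
    if labels.shape[0] != phase.n_sources:
        raise ValueError("one label per source required")
    if any(lab is None for lab in labels.tolist()):
        raise ValueError("unlabelled source: mask unlabelled sources out "
                         "before connectivity")
    area_names = sorted(set(labels.tolist()))
    groups = {a: np.flatnonzero(labels == a) for a in area_names}
    for a, idx in groups.items():
        if idx.size == 0:
            raise ValueError(f"area {a} has no sources")
    src_plv = _pairwise_plv_matrix(phase.phase)
    n = len(area_names)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            block = src_plv[np.ix_(groups[area_names[i]], groups[area_names[j]])]
            out[i, j] = out[j, i] = block.mean()
    return AreaConnectivity(out, area_names,
                            {a: int(groups[a].size) for a in area_names},
                            n_epochs_used=phase.n_epochs)


def plv_significance(plv: float, t_effective: int) -> float:
    """P-value of a PLV under the null of independent uniform phases.

    Rayleigh resultant test on the T phase-difference phasors, using the
    standard small-sample correction of the exponential approximation
    (Zar 1999); monotone decreasing in PLV at fixed T.
    """
    if not 0.0 <= plv <= 1.0:
        raise ValueError("plv must be in [0, 1]")
    if t_effective < 2:
        raise ValueError("need at least 2 samples")
    n = float(t_effective)
    rbar_n = n * plv
    z = n * plv**2
    arg = np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - rbar_n**2)) - (1.0 + 2.0 * n)
    return float(min(1.0, np.exp(arg)))


def effective_samples(T: int, band_width: float, rate: float) -> int:
    """Deflate nominal T by the band-limited autocorrelation: a signal of
    bandwidth W sampled at ``rate`` carries roughly T·(2W/rate) independent
    samples."""
    return max(2, int(round(T * 2.0 * band_width / rate)))


def rsn_average(conn: AreaConnectivity, rsn: RSNDefinition) -> float:
    """Mean PLV over the n·(n−1)/2 within-network area pairs."""
    missing = [m for m in rsn.members if m not in conn.area_names]
    if missing:
        raise KeyError(f"network {rsn.name} members missing from "
                       f"connectivity: {missing}")
    idx = [conn.area_names.index(m) for m in rsn.members]
    vals = [conn.plv[i, j] for k, i in enumerate(idx) for j in idx[k + 1:]]
    return float(np.mean(vals))
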