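"""Analytic single-sphere MEG forward model.

The magnetic field of a current dipole inside a spherically symmetric
conductor has a closed form (Sarvas 1987): volume currents contribute no
radial field, and the full vector field outside the conductor is the
gradient of a scalar potential.  This is the standard desk-scale stand-in
for a BEM head model and preserves the two properties the beamformer
relies on: linearity in the dipole moment, and silence of radially
oriented sources.
"""

from __future__ import annotations

import numpy as np

MU0_OVER_4PI = 1e-7  # T·m/A


class SourceOutsideSphereError(ValueError):
    """A source lies at or beyond the sensor shell."""


def _check_geometry(source_positions: np.ndarray, sensor_positions: np.ndarray,
                    center: np.ndarray) -> None:
    src_r = np.linalg.norm(source_positions - center, axis=1)
    sens_r = np.linalg.norm(sensor_positions - center, axis=1)
    if np.any(src_r >= sens_r.min()):
        bad = int(np.argmax(src_r))
        raise SourceOutsideSphereError(
            f"source {bad} at radius {src_r[bad]:.4f} m is not strictly inside "
            f"the sensor shell (min sensor radius {sens_r.min():.4f} m)")


def sarvas_field(source_pos: np.ndarray, moment: np.ndarray,
                 sensor_pos: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Magnetic field B (tesla) of a current dipole in a spherical conductor.

    Parameters
    ----------
    source_pos : (3,) dipole location, meters.
    moment : (3,) dipole moment, A·m.
    sensor_pos : (n, 3) field evaluation points, meters.
    center : (3,) sphere center; origin if omitted.

    Returns
    -------
    (n, 3) field vectors.  The field is exactly zero for a dipole at the
    center and for a radially oriented dipole.
    """
    if center is None:
        center = np.zeros(3)
    r0 = np.asarray(source_pos, float) - center
    q = np.asarray(moment, float)
    r = np.atleast_2d(np.asarray(sensor_pos, float)) - center

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field requested at the source location")
    ar = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn**2 - np.einsum("j,ij->i", r0, r))
    # grad F = (a²/r + a·r/a + 2a + 2r)·r − (a + 2r + a·r/a)·r0
    c1 = a**2 / rn + ar / a + 2.0 * a + 2.0 * rn
    c2 = a + 2.0 * rn + ar / a
    grad_f = c1[:, None] * r - c2[:, None] * r0

    qxr0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * qxr0 - (r @ qxr0)[:, None] * grad_f)
    return b


def magnetic_scalar_potential(source_pos: np.ndarray, moment: np.ndarray,
                              points: np.ndarray,
                              center: np.ndarray | None = None) -> np.ndarray:
    """Scalar potential U with B = −μ0·∇U outside the conductor.

    Kept separate from :func:`sarvas_field` so the analytic gradient can be
    validated against a finite-difference gradient of U.
    """
    if center is None:
        center = np.zeros(3)
    r0 = np.asarray(source_pos, float) - center
    q = np.asarray(moment, float)
    r = np.atleast_2d(np.asarray(points, float)) - center
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    f = a * (rn * a + rn**2 - r @ r0)
    return -(np.cross(q, r0) @ r.T).ravel() / (4.0 * np.pi * f)


def leadfield_matrix(source_positions: np.ndarray,
                     sensor_positions: np.ndarray,
                     sensor_orientations: np.ndarray,
                     source_orientations: np.ndarray | None = None,
                     center: np.ndarray | None = None,
                     check: bool = True) -> np.ndarray:
    """Leadfield of unit dipoles at magnetometer sensors.

    Returns (n_sensors, n_sources) if ``source_orientations`` is given
    (fixed scalar orientation per source), else (n_sensors, n_sources, 3)
    with one column per Cartesian moment component.
    """
    if center is None:
        center = np.zeros(3)
    source_positions = np.asarray(source_positions, float)
    sensor_positions = np.asarray(sensor_positions, float)
    sensor_orientations = np.asarray(sensor_orientations, float)
    if check:
        _check_geometry(source_positions, sensor_positions, center)
    n_src = source_positions.shape[0]
    n_sens = sensor_positions.shape[0]
    free = np.empty((n_sens, n_src, 3))
    eye = np.eye(3)
    for s in range(n_src):
        for c in range(3):
            b = sarvas_field(source_positions[s], eye[c], sensor_positions, center)
            free[:, s, c] = np.einsum("ij,ij->i", b, sensor_orientations)
    if source_orientations is None:
        return free
    source_orientations = np.asarray(source_orientations, float)
    return np.einsum("nsc,sc->ns", free, source_orientations)
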