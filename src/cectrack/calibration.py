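"""Gas-phase training grids and least-squares calibration of f_CT(delta).

The charge-transfer factor between a protonated species and a water is
modeled as f_CT = exp(k (delta - delta_0)). The (k, delta_0) pair is fitted
to tabulated factors computed externally (e.g. CDFT-CI scans) on grids of
collinear donor-H-acceptor geometries. The electronic-structure step itself
is out of scope here: this module generates the geometries and consumes
(delta, f_CT) tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .cec_core import CTParams
from .errors import ConfigurationError, GeometryError
from .fixtures import OH_BOND, _proton_pair_frame
from .trajectory_io import Frame

__all__ = [
    "TrainingGrid",
    "FitResult",
    "generate_h3o_water_grid",
    "generate_glu_water_grid",
    "fit_ct_parameters",
    "H3O_ROO_VALUES",
    "GLU_ROO_VALUES",
]

H3O_ROO_VALUES = (2.2, 2.4, 2.6, 2.8, 3.0, 3.2)
GLU_ROO_VALUES = tuple(np.round(np.linspace(2.2, 2.8, 7), 10))


@dataclass
class TrainingGrid:
    """Scan geometries with their transfer coordinates and (r_OO, r_OH) labels."""

    geometries: list[Frame]
    deltas: np.ndarray
    labels: list[tuple[float, float]]
    pair_kind: str

    def __len__(self) -> int:
        return len(self.geometries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_oo": [l[0] for l in self.labels],
                "r_oh": [l[1] for l in self.labels],
                "delta": self.deltas,
            }
        )


def generate_h3o_water_grid(
    roo_values: tuple[float, ...] = H3O_ROO_VALUES,
    n_h_positions: int = 6,
) -> TrainingGrid:
    """Hydronium-water scan: for each O-O distance, shared-proton positions
    evenly spaced from r_OH = 0.9 A to the midpoint r_OO / 2 (inclusive)."""
    geoms, deltas, labels = [], [], []
    for r_oo in roo_values:
        if r_oo <= 1.8:
            raise GeometryError(f"r_OO = {r_oo} A is below the supported range")
        if r_oo / 2 <= 0.9:
            raise GeometryError(
                f"r_OO = {r_oo} A leaves no room between 0.9 A and the midpoint"
            )
        for r_oh in np.linspace(0.9, r_oo / 2, n_h_positions):
            fr = _proton_pair_frame(
                r_oo,
                float(r_oh),
                index=len(geoms),
                comment=f"grid pair=h3o-water r_oo={r_oo:.6g} r_oh={r_oh:.6f}",
            )
            geoms.append(fr)
            deltas.append(2 * r_oh - r_oo)
            labels.append((float(r_oo), float(r_oh)))
    return TrainingGrid(
        geometries=geoms, deltas=np.array(deltas), labels=labels, pair_kind="h3o-water"
    )


def _glu_pair_frame(r_oo, r_oh, index=0, comment=""):
    """Idealized planar carboxyl donating its proton to a water along x."""
    c = np.array([-1.32 * np.cos(np.deg2rad(30)), 1.32 * np.sin(np.deg2rad(30)), 0.0])
    o2 = c + 1.21 * np.array([-np.cos(np.deg2rad(80)), np.sin(np.deg2rad(80)), 0.0])
    wa = np.deg2rad(52.0)
    water_o = np.array([r_oo, 0.0, 0.0])
    water_h = [
        water_o + OH_BOND * np.array([np.cos(wa), s * np.sin(wa), 0.0]) for s in (+1, -1)
    ]
    elements = ["C", "O", "O", "H", "O", "H", "H"]
    positions = np.array(
        [c, np.zeros(3), o2, [r_oh, 0.0, 0.0], water_o, water_h[0], water_h[1]]
    )
    return Frame(elements=elements, positions=positions, index=index, comment=comment)


def generate_glu_water_grid(
    roo_values: tuple[float, ...] = GLU_ROO_VALUES,
    n_h_positions: int = 9,
) -> TrainingGrid:
    """Carboxyl-water scan: shared-proton r_OH evenly in [1.0, r_OO - 1.0] A."""
    geoms, deltas, labels = [], [], []
    for r_oo in roo_values:
        if r_oo <= 2.0:
            raise GeometryError(
                f"r_OO = {r_oo} A leaves no room between 1.0 A and r_OO - 1.0 A"
            )
        for r_oh in np.linspace(1.0, r_oo - 1.0, n_h_positions):
            fr = _glu_pair_frame(
                r_oo,
                float(r_oh),
                index=len(geoms),
                comment=f"grid pair=glu-water r_oo={r_oo:.6g} r_oh={r_oh:.6f}",
            )
            geoms.append(fr)
            deltas.append(2 * r_oh - r_oo)
            labels.append((float(r_oo), float(r_oh)))
    return TrainingGrid(
        geometries=geoms, deltas=np.array(deltas), labels=labels, pair_kind="glu-water"
    )


@dataclass
class FitResult:
    """Least-squares estimate of the exponential charge-transfer model."""

    k: float
    delta0: float
    residual_rms: float
    n_points: int
    covariance: np.ndarray  # 2x2, (k, delta0) order

    def stderr(self) -> tuple[float, float]:
        d = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return float(d[0]), float(d[1])

    def to_ct_params(self, pair_kind: str, functional: str = "fit") -> CTParams:
        return CTParams(pair_kind=pair_kind, k=self.k, delta0=self.delta0, functional=functional)


def fit_ct_parameters(
    deltas,
    fct_values,
    weights=None,
    fix_delta0: bool = False,
    log_space: bool = False,
) -> FitResult:
    """Fit f_CT = exp(k (delta - delta_0)) by least squares.

    The fit is initialized from the exact log-linear regression
    ln f = k delta - k delta_0 and then refined on the factor itself
    (``log_space=True`` keeps the linear log-space solution, which is what a
    symmetric-noise-in-log model calls for). ``fix_delta0`` pins
    delta_0 = 0, appropriate for symmetric pairs where c1^2 = c2^2 at equal
    sharing. ``weights`` multiply the residuals.
    """
    d = np.asarray(deltas, dtype=float)
    f = np.asarray(fct_values, dtype=float)
    if d.shape != f.shape or d.ndim != 1:
        raise ValueError("deltas and fct_values must be 1-D arrays of equal length")
    if len(d) < 3:
        raise ConfigurationError("need at least 3 points to fit (k, delta0)")
    if np.any(f <= 0):
        raise ConfigurationError("charge-transfer factors must be positive")
    if np.ptp(d) < 1e-12:
        raise ConfigurationError("all deltas identical: (k, delta0) unidentifiable")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)

    logf = np.log(f)
    # weighted linear init: logf = k*d + b, delta0 = -b/k
    A = np.vstack([d, np.ones_like(d)]).T * w[:, None]
    sol, *_ = np.linalg.lstsq(A, logf * w, rcond=None)
    k0 = float(sol[0])
    if k0 <= 0:
        raise ConfigurationError("data decrease with delta; k > 0 model cannot fit")
    b0 = float(sol[1])
    delta0_init = 0.0 if fix_delta0 else -b0 / k0

    if log_space:
        if fix_delta0:
            # one-parameter weighted regression through the origin
            k_hat = float(np.sum(w**2 * d * logf) / np.sum(w**2 * d * d))
            resid = (logf - k_hat * d) * w
            dof = max(len(d) - 1, 1)
            s2 = float(resid @ resid) / dof
            var_k = s2 / float(np.sum(w**2 * d * d))
            cov = np.array([[var_k, 0.0], [0.0, 0.0]])
            k_fit, d0_fit = k_hat, 0.0
        else:
            resid = A @ sol - logf * w
            dof = max(len(d) - 2, 1)
            s2 = float(resid @ resid) / dof
            cov_lin = s2 * np.linalg.inv(A.T @ A)  # covariance of (k, b)
            # delta0 = -b/k: propagate via the Jacobian [b/k^2, -1/k]
            J = np.array([[1.0, 0.0], [b0 / k0**2, -1.0 / k0]])
            cov = J @ cov_lin @ J.T
            k_fit, d0_fit = k0, -b0 / k0
        rms = float(np.sqrt(np.mean(resid**2)))
        return FitResult(k=k_fit, delta0=d0_fit, residual_rms=rms, n_points=len(d), covariance=cov)

    sigma = 1.0 / w
    with warnings.catch_warnings():
        # zero-residual (noiseless) fits have a singular covariance; the
        # returned inf entries are handled downstream
        warnings.simplefilter("ignore", OptimizeWarning)
        if fix_delta0:
            popt, pcov = curve_fit(
                lambda x, k: np.exp(np.clip(k * x, -50, 50)), d, f, p0=[k0], sigma=sigma
            )
            k_fit, d0_fit = float(popt[0]), 0.0
            cov = np.zeros((2, 2))
            cov[0, 0] = pcov[0, 0]
        else:
            popt, pcov = curve_fit(
                lambda x, k, d0: np.exp(np.clip(k * (x - d0), -50, 50)),
                d,
                f,
                p0=[k0, delta0_init],
                sigma=sigma,
                maxfev=10000,
            )
            k_fit, d0_fit = float(popt[0]), float(popt[1])
            cov = pcov
    if k_fit <= 0:
        raise ConfigurationError(f"fitted k = {k_fit} is not positive")
    resid = (np.exp(np.clip(k_fit * (d - d0_fit), -50, 50)) - f) * w
    rms = float(np.sqrt(np.mean(resid**2)))
    return FitResult(k=k_fit, delta0=d0_fit, residual_rms=rms, n_points=len(d), covariance=np.asarray(cov))
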