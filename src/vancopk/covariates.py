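"""Additive linear covariate model for individual PK parameters.

The population model maps a patient's covariates to typical clearance and
volume through raw-unit linear equations, and adds a bivariate normal random
effect:

    (CL_i, V_i) = (z_cl·θ_cl, z_v·θ_v) + η_i,    η_i ~ N(0, Ω)

Categorical covariates keep the source coding (1/2, not 0/1) so published
coefficient vectors are usable verbatim.  The published final and basic
models ship as YAML assets (see :func:`load_published_model`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .pk import PKParams

__all__ = [
    "CovariateVector",
    "CovariateSelection",
    "PopulationModel",
    "CATEGORICAL_COVARIATES",
    "CONTINUOUS_COVARIATES",
    "ALL_COVARIATES",
    "design_row",
    "predict_typical",
    "individual_params",
    "load_published_model",
]

# 1/2 coded flags: 1 = not used / male / Eli Lilly / CRRT-treated / severe burn
CATEGORICAL_COVARIATES = (
    "DA", "NE", "furosemide", "dobutamine", "sex", "VM", "CRRT_S", "Burn_S",
)
CONTINUOUS_COVARIATES = ("Cr", "age", "TBW")
ALL_COVARIATES = CATEGORICAL_COVARIATES + CONTINUOUS_COVARIATES


class CovariateError(ValueError):
    """Raised for unknown covariate names or out-of-range values."""


class ImplausibleCovariateError(ValueError):
    """Raised when a covariate equation predicts nonpositive CL or V."""


@dataclass(frozen=True)
class CovariateVector:
    """The eleven screened patient covariates.

    Drug-exposure flags (DA = dopamine, NE = noradrenaline, furosemide,
    dobutamine) are coded 1 if not used, 2 if used.  sex: 1 male, 2 female.
    VM (manufacturer): 1 Eli Lilly, 2 Xinchang.  CRRT_S: 1 on CRRT, 2 not.
    Burn_S: 1 severe burn (>50%, acute convalescence), 2 otherwise.
    Cr: serum creatinine (μmol/L); age (years); TBW: total body weight (kg).
    """

    DA: int = 1
    NE: int = 1
    furosemide: int = 1
    dobutamine: int = 1
    sex: int = 1
    VM: int = 1
    CRRT_S: int = 2
    Burn_S: int = 2
    Cr: float = 71.0
    age: float = 62.0
    TBW: float = 65.0

    def __post_init__(self) -> None:
        for name in CATEGORICAL_COVARIATES:
            if getattr(self, name) not in (1, 2):
                raise CovariateError(
                    f"{name} must be coded 1 or 2, got {getattr(self, name)}"
                )
        if not self.Cr > 0:
            raise CovariateError(f"Cr must be > 0, got {self.Cr}")
        if self.age < 18:
            raise CovariateError(f"age must be >= 18 (adults only), got {self.age}")
        if not self.TBW > 0:
            raise CovariateError(f"TBW must be > 0, got {self.TBW}")

    def __getitem__(self, name: str) -> float:
        if name not in ALL_COVARIATES:
            raise CovariateError(f"unknown covariate {name!r}")
        return float(getattr(self, name))


@dataclass(frozen=True)
class CovariateSelection:
    """Ordered covariate names entering the CL and V equations."""

    cl_covariates: tuple[str, ...] = ()
    v_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for names in (self.cl_covariates, self.v_covariates):
            for name in names:
                if name not in ALL_COVARIATES:
                    raise CovariateError(f"unknown covariate {name!r}")
            if len(set(names)) != len(names):
                raise CovariateError(f"duplicate covariate in selection {names}")
        object.__setattr__(self, "cl_covariates", tuple(self.cl_covariates))
        object.__setattr__(self, "v_covariates", tuple(self.v_covariates))


@dataclass
class PopulationModel:
    """Population PK model: covariate coefficients, IIV covariance, residual.

    ``theta_cl``/``theta_v`` are [intercept, one coefficient per selected
    covariate, in selection order].  ``omega`` is the 2×2 covariance of the
    additive random effects (η_CL, η_V).  The residual model is either
    ``proportional`` (``residual_scale`` = CV as a fraction, with a small
    additive SD floor so near-zero observations keep finite weight) or
    ``additive`` (``residual_scale`` = SD in μg/ml).
    """

    selection: CovariateSelection
    theta_cl: np.ndarray
    theta_v: np.ndarray
    omega: np.ndarray
    residual_model: str = "proportional"
    residual_scale: float = 0.15
    additive_floor: float = 0.5  # μg/ml; ignored for purely additive error
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.theta_cl = np.atleast_1d(np.asarray(self.theta_cl, dtype=float))
        self.theta_v = np.atleast_1d(np.asarray(self.theta_v, dtype=float))
        self.omega = np.asarray(self.omega, dtype=float)
        if self.theta_cl.shape != (1 + len(self.selection.cl_covariates),):
            raise CovariateError(
                f"theta_cl length {self.theta_cl.size} does not match "
                f"selection {self.selection.cl_covariates}"
            )
        if self.theta_v.shape != (1 + len(self.selection.v_covariates),):
            raise CovariateError(
                f"theta_v length {self.theta_v.size} does not match "
                f"selection {self.selection.v_covariates}"
            )
        if self.omega.shape != (2, 2):
            raise CovariateError(f"omega must be 2x2, got {self.omega.shape}")
        if not np.allclose(self.omega, self.omega.T):
            raise CovariateError("omega must be symmetric")
        if np.linalg.eigvalsh(self.omega).min() < -1e-10:
            raise CovariateError("omega must be positive semidefinite")
        if self.residual_model not in ("proportional", "additive"):
            raise CovariateError(f"unknown residual model {self.residual_model!r}")
        if not self.residual_scale > 0:
            raise CovariateError("residual_scale must be > 0")

    # -- residual error -------------------------------------------------
    def residual_sd(self, conc) -> np.ndarray:
        """Residual SD at a concentration (observed or predicted scale)."""
        conc = np.asarray(conc, dtype=float)
        if self.residual_model == "additive":
            return np.full_like(conc, self.residual_scale)
        return np.sqrt(self.additive_floor**2 + (self.residual_scale * conc) ** 2)

    def iiv_cv_percent(self, reference: PKParams) -> tuple[float, float]:
        """IIV CV% of CL and V relative to a reference typical value."""
        sd = np.sqrt(np.diag(self.omega))
        return 100.0 * sd[0] / reference.cl, 100.0 * sd[1] / reference.v

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cl_covariates": list(self.selection.cl_covariates),
            "v_covariates": list(self.selection.v_covariates),
            "theta_cl": [float(x) for x in self.theta_cl],
            "theta_v": [float(x) for x in self.theta_v],
            "omega": [[float(x) for x in row] for row in self.omega],
            "residual_model": self.residual_model,
            "residual_scale": float(self.residual_scale),
            "additive_floor": float(self.additive_floor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            selection=CovariateSelection(
                tuple(d.get("cl_covariates", ())), tuple(d.get("v_covariates", ()))
            ),
            theta_cl=np.asarray(d["theta_cl"], dtype=float),
            theta_v=np.asarray(d["theta_v"], dtype=float),
            omega=np.asarray(d["omega"], dtype=float),
            residual_model=d.get("residual_model", "proportional"),
            residual_scale=float(d.get("residual_scale", 0.15)),
            additive_floor=float(d.get("additive_floor", 0.5)),
            name=d.get("name", "unnamed"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)


def design_row(
    cov: CovariateVector, selection: CovariateSelection
) -> tuple[np.ndarray, np.ndarray]:
    """Design (Z) rows for the CL and V equations: [1, covariates...]."""
    z_cl = np.array([1.0] + [cov[name] for name in selection.cl_covariates])
    z_v = np.array([1.0] + [cov[name] for name in selection.v_covariates])
    return z_cl, z_v


def predict_typical(model: PopulationModel, cov: CovariateVector) -> PKParams:
    """Typical (population-predicted) CL and V for a covariate vector."""
    z_cl, z_v = design_row(cov, model.selection)
    cl = float(z_cl @ model.theta_cl)
    v = float(z_v @ model.theta_v)
    if cl <= 0 or v <= 0:
        raise ImplausibleCovariateError(
            f"covariate equation predicts nonpositive parameters "
            f"(CL={cl:.4g} L/h, V={v:.4g} L) for {cov}"
        )
    return PKParams(cl, v)


def positivity_floor(typical: float) -> float:
    """Lower clamp for additive random effects: max(0.01, 5% of typical)."""
    return max(0.01, 0.05 * typical)


def individual_params(
    model: PopulationModel, cov: CovariateVector, eta
) -> tuple[PKParams, bool]:
    """Typical values plus additive random effects, clamped to stay positive.

    Returns (params, truncated) where ``truncated`` flags that at least one
    parameter hit the positivity floor.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (2,) or not np.all(np.isfinite(eta)):
        raise CovariateError(f"eta must be two finite values, got {eta}")
    typ = predict_typical(model, cov)
    cl = typ.cl + eta[0]
    v = typ.v + eta[1]
    floor_cl = positivity_floor(typ.cl)
    floor_v = positivity_floor(typ.v)
    truncated = cl < floor_cl or v < floor_v
    return PKParams(max(cl, floor_cl), max(v, floor_v)), truncated


def load_published_model(which: str = "final") -> PopulationModel:
    """Load the packaged published model asset ("final" or "basic")."""
    if which not in ("final", "basic"):
        raise ValueError(f"which must be 'final' or 'basic', got {which!r}")
    ref = importlib.resources.files("vancopk") / "assets" / f"published_{which}_model.yaml"
    return PopulationModel.from_dict(yaml.safe_load(ref.read_text()))
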