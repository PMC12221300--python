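"""Model family, parameter transforms, value scaling and drift equations.

The model family is a nested sequence of drift-diffusion variants for binary
multi-attribute choice (two options i, j; two attributes taste T and health H):

* ``DDM``       — drift proportional to the gaze-free weighted value difference
  ``VD = omega*(T_i - T_j) + (1-omega)*(H_i - H_j)``.
* ``aDDM``      — the currently unfixated *option* is discounted by ``theta``;
  the option-level dwell shares ``f_i, f_j`` weight the two gaze states.
* ``maaDDM``    — additionally the unfixated *attribute* is discounted by a
  common ``phi``; the four attribute-level dwell shares weight the terms.
* ``maaDDM2phi``— separate attribute discounts ``phi_t`` (taste) and ``phi_h``
  (health).

Each variant also exists in an ``sp`` version that estimates the relative
starting point ``beta`` instead of fixing it at 0.5.  Option *i* is the tasty
option and maps to the upper boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "ModelSpec",
    "ParamSet",
    "MODEL_NAMES",
    "model_registry",
    "softplus",
    "inv_softplus",
    "probit",
    "constrain_params",
    "scale_values",
    "value_difference",
]

#: canonical ordering of raw parameters
PARAM_ORDER = ("alpha", "ndt", "d", "omega", "beta", "theta", "phi", "phi_t", "phi_h")

#: transforms applied to raw (unconstrained) parameter values
POSITIVE_PARAMS = ("alpha", "ndt")       # softplus
UNIT_PARAMS = ("omega", "beta")          # standard normal CDF
IDENTITY_PARAMS = ("d", "theta", "phi", "phi_t", "phi_h")


def softplus(x):
    """Numerically stable ``log(1 + exp(x))``."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def inv_softplus(y):
    """Inverse of :func:`softplus` for y > 0."""
    y = np.asarray(y, dtype=float)
    # log(e^y - 1) = y + log1p(-exp(-y))
    return y + np.log(-np.expm1(-y))


def probit(x):
    """Standard normal CDF, mapping raw values into (0, 1)."""
    return ndtr(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters a model variant estimates, and fixed values otherwise.

    ``estimated`` lists raw parameter names in canonical order.  ``fixed``
    supplies constrained-scale values for everything else (``beta`` defaults
    to 0.5 when not estimated; ``theta`` and the attribute discounts default
    to 1, which switches the corresponding discounting off).
    """

    name: str
    estimated: tuple[str, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.estimated) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        est = set(self.estimated)
        if "phi_h" in est and "phi_t" not in est:
            raise ValueError("phi_h requires phi_t (two-discount models estimate both)")
        if ("phi" in est or "phi_t" in est) and "theta" not in est:
            raise ValueError("attribute discounts require the option discount theta")

    @property
    def n_params(self) -> int:
        return len(self.estimated)

    def validate_params(self, params: Mapping[str, object]) -> None:
        """Reject parameter values the spec neither estimates nor fixes."""
        allowed = set(self.estimated) | set(self.fixed) | {"beta", "theta", "phi", "phi_t", "phi_h"}
        extra = set(params) - set(PARAM_ORDER)
        if extra:
            raise ValueError(f"unknown parameters {sorted(extra)}")
        est = set(self.estimated)
        if "phi_t" in params and "phi" in est:
            raise ValueError(f"{self.name} uses a common phi; phi_t/phi_h not accepted")
        if "phi_h" in params and "phi" in est:
            raise ValueError(f"{self.name} uses a common phi; phi_t/phi_h not accepted")
        if ("phi" in params and params.get("phi") is not None and "phi_t" in est):
            raise ValueError(f"{self.name} estimates phi_t/phi_h separately; 'phi' not accepted")

    def to_json(self) -> dict:
        return {"name": self.name, "estimated": list(self.estimated), "fixed": dict(self.fixed)}

    @staticmethod
    def from_json(obj: Mapping) -> "ModelSpec":
        return ModelSpec(obj["name"], tuple(obj["estimated"]), dict(obj.get("fixed", {})))


_BASE = ("alpha", "ndt", "d", "omega")

_REGISTRY: dict[str, ModelSpec] = {
    "DDM": ModelSpec("DDM", _BASE, {"beta": 0.5}),
    "DDMsp": ModelSpec("DDMsp", _BASE + ("beta",)),
    "aDDM": ModelSpec("aDDM", _BASE + ("theta",), {"beta": 0.5}),
    "aDDMsp": ModelSpec("aDDMsp", _BASE + ("beta", "theta")),
    "maaDDM": ModelSpec("maaDDM", _BASE + ("theta", "phi"), {"beta": 0.5}),
    "maaDDMsp": ModelSpec("maaDDMsp", _BASE + ("beta", "theta", "phi")),
    "maaDDM2phi": ModelSpec("maaDDM2phi", _BASE + ("theta", "phi_t", "phi_h"), {"beta": 0.5}),
    "maaDDM2phi_sp": ModelSpec("maaDDM2phi_sp", _BASE + ("beta", "theta", "phi_t", "phi_h")),
}

MODEL_NAMES = tuple(_REGISTRY)


def model_registry(name: str) -> ModelSpec:
    """Return the :class:`ModelSpec` for one of the eight registered variants."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid models: {', '.join(MODEL_NAMES)}"
        ) from None


@dataclass
class ParamSet:
    """Constrained-scale parameters of one participant (or arrays thereof)."""

    alpha: np.ndarray | float
    ndt: np.ndarray | float
    d: np.ndarray | float
    omega: np.ndarray | float
    beta: np.ndarray | float = 0.5
    theta: np.ndarray | float = 1.0
    phi_t: np.ndarray | float = 1.0
    phi_h: np.ndarray | float = 1.0

    def replace(self, **kw) -> "ParamSet":
        return replace(self, **kw)


def constrain_params(spec: ModelSpec, raw: Mapping[str, object]) -> ParamSet:
    """Map raw (unconstrained) values to a constrained :class:`ParamSet`.

    ``alpha`` and ``ndt`` pass through a softplus, ``omega`` and ``beta``
    through the standard normal CDF; the drift scaling ``d`` and all
    attentional discounts are unconstrained and pass through unchanged.
    Parameters the spec does not estimate take their fixed values.
    """
    spec.validate_params(raw)
    missing = set(spec.estimated) - set(raw)
    if missing:
        raise ValueError(f"{spec.name} requires raw values for {sorted(missing)}")
    out: dict[str, object] = {}
    for name in spec.estimated:
        x = raw[name]
        if name in POSITIVE_PARAMS:
            out[name] = softplus(x)
        elif name in UNIT_PARAMS:
            out[name] = probit(x)
        else:
            out[name] = np.asarray(x, dtype=float)
    if "phi" in out:
        phi = out.pop("phi")
        out["phi_t"] = phi
        out["phi_h"] = phi
    for name, value in spec.fixed.items():
        out.setdefault(name, value)
    out.setdefault("beta", 0.5)
    return ParamSet(**out)


def scale_values(
    ratings: pd.DataFrame,
    columns: Sequence[str],
    by: str = "participant",
    lo: float = 1.0,
    hi: float = 10.0,
) -> pd.DataFrame:
    """Rescale rating columns into ``[lo, hi]`` per participant per attribute.

    The map is the affine min–max transform of each participant's ratings of
    one attribute; a degenerate (constant) rating column maps to the interval
    midpoint.  Rows with non-finite ratings are dropped and reported via the
    returned frame's ``attrs['rejected_rows']``.
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    df = ratings.copy()
    finite = np.isfinite(df[list(columns)].to_numpy(dtype=float)).all(axis=1)
    rejected = df.index[~finite]
    df = df.loc[finite].copy()

    def _scale(col: pd.Series) -> pd.Series:
        x = col.to_numpy(dtype=float)
        rng = x.max() - x.min()
        if rng == 0:
            return pd.Series(np.full(x.shape, (lo + hi) / 2.0), index=col.index)
        return pd.Series(lo + (hi - lo) * (x - x.min()) / rng, index=col.index)

    for c in columns:
        df[c] = df.groupby(by, group_keys=False)[c].apply(_scale)
    df.attrs["rejected_rows"] = list(rejected)
    return df


def value_difference(spec, params: ParamSet, values, dwell):
    """Signed value difference VD (option i positive) under gaze discounting.

    ``values = (t_i, t_j, h_i, h_j)`` are scaled attribute values and
    ``dwell = (f_it, f_ih, f_jt, f_jh)`` the relative dwell shares on the four
    option-by-attribute screen regions.  With ``w = omega``::

        VD = f_it * ( w      (T_i - th T_j) + (1-w) ph_H (H_i - th H_j) )
           + f_ih * ( w ph_T (T_i - th T_j) + (1-w)      (H_i - th H_j) )
           + f_jt * ( w      (th T_i - T_j) + (1-w) ph_H (th H_i - H_j) )
           + f_jh * ( w ph_T (th T_i - T_j) + (1-w)      (th H_i - H_j) )

    Setting ``phi_t = phi_h`` recovers the common-discount model, ``phi = 1``
    the option-level model, and ``theta = 1`` the gaze-free weighted
    difference.  The mean drift of a trial is ``d * VD``.
    """
    t_i, t_j, h_i, h_j = (np.asarray(v, dtype=float) for v in values)
    f_it, f_ih, f_jt, f_jh = (np.asarray(f, dtype=float) for f in dwell)
    w, th = params.omega, params.theta
    ph_t, ph_h = params.phi_t, params.phi_h
    dt_i = t_i - th * t_j          # taste contrast while fixating option i
    dh_i = h_i - th * h_j
    dt_j = th * t_i - t_j          # ... while fixating option j
    dh_j = th * h_i - h_j
    return (
        f_it * (w * dt_i + (1 - w) * ph_h * dh_i)
        + f_ih * (w * ph_t * dt_i + (1 - w) * dh_i)
        + f_jt * (w * dt_j + (1 - w) * ph_h * dh_j)
        + f_jh * (w * ph_t * dt_j + (1 - w) * dh_j)
    )
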