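"""Dyad-level questionnaire scores generated from a serial path model.

The generative chain mirrors the structural model the analysis estimates:

    X  (interbrain coupling, standardized)
    M1 (sense of joint control)        = a1*X + e1
    M2 (delta shared intentionality)   = a2*X + d21*M1 + e2
    M3 (delta perceived similarity)    = a3*X + d31*M1 + d32*M2 + e3
    Y  (delta social connectedness)    = c'*X + b1*M1 + b2*M2 + b3*M3 + e4

By default scores are emitted on this standardized scale (pre ~ N(0,1),
post = pre + delta) so estimator-recovery tests are not distorted by
censoring; Likert mode maps everything onto the 1-9 questionnaire scale and
clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCORE_COLUMNS = ["dyad_id", "group", "sc_pre", "sc_post", "si_pre", "si_post",
                 "ps_pre", "ps_post", "joint_control", "coupling_band"]

#: Default path coefficients, anchored to the observed correlation structure
#: between band coupling, joint control and the questionnaire deltas in the
#: kind of dyadic feedback experiment this package emulates.
STUDY_PATHS = dict(a1=0.3, a2=0.1, a3=0.0, d21=0.5, d31=0.1, d32=0.3,
                   b1=0.25, b2=0.35, b3=0.2, c_prime=0.0)


@dataclass(frozen=True)
class PathModel:
    """Coefficients and noise of the serial three-mediator model."""

    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    d21: float = 0.0
    d31: float = 0.0
    d32: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    c_prime: float = 0.0
    residual_sds: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    n_dyads: int = 57
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.residual_sds):
            raise ValueError("residual SDs must be positive")
        coefs = (self.a1, self.a2, self.a3, self.d21, self.d31, self.d32,
                 self.b1, self.b2, self.b3, self.c_prime)
        if not all(np.isfinite(coefs)):
            raise ValueError("path coefficients must be finite")

    @classmethod
    def study_like(cls, **overrides) -> "PathModel":
        """Model with the default study-like coefficients."""
        kw = dict(STUDY_PATHS,
                  residual_sds=(0.95, 0.85, 0.9, 0.8))
        kw.update(overrides)
        return cls(**kw)


def path_matrix(model: PathModel) -> np.ndarray:
    """Lower-triangular coefficient matrix B with variable order
    (X, M1, M2, M3, Y), so v = B v + e."""
    B = np.zeros((5, 5))
    B[1, 0] = model.a1
    B[2, 0], B[2, 1] = model.a2, model.d21
    B[3, 0], B[3, 1], B[3, 2] = model.a3, model.d31, model.d32
    B[4, 0], B[4, 1], B[4, 2], B[4, 3] = (model.c_prime, model.b1,
                                          model.b2, model.b3)
    return B


def implied_covariance(model: PathModel) -> np.ndarray:
    """Model-implied covariance of (X, M1, M2, M3, Y): (I-B)^-1 Psi (I-B)^-T."""
    B = path_matrix(model)
    psi = np.diag([1.0, *(s ** 2 for s in model.residual_sds)])
    inv = np.linalg.inv(np.eye(5) - B)
    return inv @ psi @ inv.T


def simulate_structural(model: PathModel,
                        x: np.ndarray | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw (X, M1, M2, M3, Y) from the path model.

    ``x`` overrides the standard-normal draw of the exogenous coupling
    variable (it is used as given, not re-standardized).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    n = model.n_dyads if x is None else len(x)
    if n < 4:
        raise ValueError("need at least 4 dyads")
    X = rng.standard_normal(n) if x is None else np.asarray(x, dtype=float)
    s1, s2, s3, s4 = model.residual_sds
    M1 = model.a1 * X + s1 * rng.standard_normal(n)
    M2 = model.a2 * X + model.d21 * M1 + s2 * rng.standard_normal(n)
    M3 = (model.a3 * X + model.d31 * M1 + model.d32 * M2
          + s3 * rng.standard_normal(n))
    Y = (model.c_prime * X + model.b1 * M1 + model.b2 * M2 + model.b3 * M3
         + s4 * rng.standard_normal(n))
    return pd.DataFrame({"X": X, "M1": M1, "M2": M2, "M3": M3, "Y": Y})


def simulate_scores(model: PathModel,
                    coupling: np.ndarray | None = None,
                    groups: np.ndarray | None = None,
                    likert: bool = False,
                    delta_intercepts: tuple[float, float, float] = (0.0, 0.0, 0.0),
                    baseline_mean: float = 5.0,
                    baseline_sd: float = 1.0,
                    likert_scale: float = 1.5,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit a dyad-level score table from the path model.

    The structural deltas drive post = pre + delta for shared intentionality
    (M2), perceived similarity (M3) and social connectedness (Y); joint
    control (M1) is post-only. ``delta_intercepts`` adds a common offset to
    (M2, M3, Y) deltas, giving a main effect of time. In Likert mode the
    standardized quantities are placed on the 1-9 scale (pre ~
    N(baseline_mean, baseline_sd), deltas and joint control scaled by
    ``likert_scale``) and clipped to [1, 9]; default is the unclipped
    standardized scale.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(model.seed))
    sem = simulate_structural(model, x=coupling, rng=rng)
    n = len(sem)
    if groups is None:
        groups = np.array(["real"] * n)
    d_si = sem["M2"].to_numpy() + delta_intercepts[0]
    d_ps = sem["M3"].to_numpy() + delta_intercepts[1]
    d_sc = sem["Y"].to_numpy() + delta_intercepts[2]
    jc = sem["M1"].to_numpy()

    if likert:
        pre = {k: np.clip(baseline_mean + baseline_sd * rng.standard_normal(n),
                          1.0, 9.0) for k in ("sc", "si", "ps")}
        post = {k: np.clip(pre[k] + likert_scale * d, 1.0, 9.0)
                for k, d in (("sc", d_sc), ("si", d_si), ("ps", d_ps))}
        jc_out = np.clip(baseline_mean + likert_scale * jc, 1.0, 9.0)
    else:
        pre = {k: rng.standard_normal(n) for k in ("sc", "si", "ps")}
        post = {"sc": pre["sc"] + d_sc, "si": pre["si"] + d_si,
                "ps": pre["ps"] + d_ps}
        jc_out = jc

    return pd.DataFrame({
        "dyad_id": [f"dyad_{i:03d}" for i in range(n)],
        "group": groups,
        "sc_pre": pre["sc"], "sc_post": post["sc"],
        "si_pre": pre["si"], "si_post": post["si"],
        "ps_pre": pre["ps"], "ps_post": post["ps"],
        "joint_control": jc_out,
        "coupling_band": sem["X"].to_numpy(),
    })[SCORE_COLUMNS]
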