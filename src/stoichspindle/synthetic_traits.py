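"""Synthetic trait tables with the covariance structure of each
candidate size-control model, for validating the signature tests without
experimental data.

Each generator draws per-line latent factors and produces the observed
traits (IL, FL, ER, CD, CL, CA) at magnitudes typical of the one-cell
nematode embryo (CL ~ 50 um, FL ~ 24 um, IL ~ 11 um):

- ``timer``: IL and the elongation extent Delta are independent;
  FL = IL + Delta, so IL and FL are positively correlated.
- ``limiting_component``: component density and cell volume vary
  independently; FL increases with the total amount density x volume,
  and cell length/area derive from volume, so FL correlates with CA
  even at fixed CL.
- ``boundary``: cell length and the pole-to-cortex distance CD vary
  independently and FL = CL - 2 CD (+ noise), so FL rises with CL and
  falls with CD.
- ``custom_covariance``: multivariate normal with a user covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["GeneratorSpec", "generate_trait_table"]

_DEFAULT_MEANS = {"CL": 50.0, "FL": 24.0, "IL": 11.0, "CD": 10.0, "CA": 1150.0}


@dataclass(frozen=True)
class GeneratorSpec:
    model_kind: str = "boundary"
    n_lines: int = 200
    n_replicates: int = 1
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    line_sd: float = 1.0  # SD of the independent latent factors (um)
    noise_sd: float = 0.3  # residual/measurement noise (um)
    covariance: Optional[np.ndarray] = None  # for custom_covariance
    trait_names: tuple = ("IL", "FL", "CL", "CA", "CD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in (
            "timer",
            "limiting_component",
            "boundary",
            "custom_covariance",
        ):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.n_lines < 10:
            raise ValueError("n_lines must be >= 10")
        if self.line_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _ca_from_cl(cl: np.ndarray, rng, shape_sd: float) -> np.ndarray:
    # midplane area of an ellipse with Ry = 15 um plus shape noise
    return np.pi * (cl / 2.0) * 15.0 + rng.normal(0, shape_sd * 15.0, size=cl.shape)


def generate_trait_table(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw a trait table (one row per line replicate) under the given
    generative model; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lines
    mu = {**_DEFAULT_MEANS, **spec.means}
    s = spec.line_sd

    if spec.model_kind == "timer":
        IL = rng.normal(mu["IL"], s, n)
        delta = rng.normal(mu["FL"] - mu["IL"], s, n)
        FL = IL + delta
        CL = rng.normal(mu["CL"], s, n)
        CA = _ca_from_cl(CL, rng, spec.noise_sd)
        CD = (CL - FL) / 2.0 + rng.normal(0, spec.noise_sd, n)
    elif spec.model_kind == "limiting_component":
        # independent genetic factors: component density, cell length,
        # cell width; the limiting amount is density x volume
        density = rng.normal(1.0, s / 10.0, n)
        CL = rng.normal(mu["CL"], s, n)
        width = rng.normal(15.0, s / 2.0, n)
        volume = (CL / mu["CL"]) * (width / 15.0) ** 2
        FL = mu["FL"] * density * volume + rng.normal(0, spec.noise_sd, n)
        CA = np.pi * (CL / 2.0) * width + rng.normal(0, spec.noise_sd * 15.0, n)
        IL = rng.normal(mu["IL"], s, n)
        CD = (CL - FL) / 2.0 + rng.normal(0, spec.noise_sd, n)
    elif spec.model_kind == "boundary":
        CL = rng.normal(mu["CL"], s, n)
        CD = rng.normal(mu["CD"], s / 2.0, n)
        FL = CL - 2.0 * CD + rng.normal(0, spec.noise_sd, n)
        IL = rng.normal(mu["IL"], s, n)
        CA = _ca_from_cl(CL, rng, spec.noise_sd)
    else:  # custom_covariance
        cov = np.asarray(spec.covariance, dtype=float)
        k = len(spec.trait_names)
        if cov.shape != (k, k):
            raise ValueError("covariance shape must match trait_names")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError("covariance must be positive definite") from err
        mean_vec = np.array([mu.get(t, 0.0) for t in spec.trait_names])
        draws = rng.multivariate_normal(mean_vec, cov, size=n, method="cholesky")
        table = pd.DataFrame(draws, columns=list(spec.trait_names))
        table["line"] = [f"L{i:04d}" for i in range(n)]
        return _replicate(table, spec, rng)

    table = pd.DataFrame({"IL": IL, "FL": FL, "CL": CL, "CA": CA, "CD": CD})
    table["ER"] = (table["FL"] - table["IL"]) / (4.0 * 40.0)
    table["line"] = [f"L{i:04d}" for i in range(n)]
    return _replicate(table, spec, rng)


def _replicate(table: pd.DataFrame, spec: GeneratorSpec, rng) -> pd.DataFrame:
    """Emulate within-line replicate measurements (line means with SE are
    then the unit of analysis, as for inbred-line panels)."""
    if spec.n_replicates <= 1:
        return table
    reps = []
    value_cols = [c for c in table.columns if c != "line"]
    for _, row in table.iterrows():
        for r in range(spec.n_replicates):
            noisy = {c: row[c] + rng.normal(0, spec.noise_sd) for c in value_cols}
            noisy["line"] = row["line"]
            noisy["replicate"] = r
            reps.append(noisy)
    return pd.DataFrame(reps)
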