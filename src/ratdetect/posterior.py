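"""Container for MCMC posterior draws.

A draw holds the global parameters (home-range hierarchy, encounter and
interaction coefficients) plus the per-rat quantities (sigma_i, delta_i,
rho_i). Both forward simulators consume this container, so a fitted
posterior and the synthetic reference posterior are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GLOBAL_PARAMS = (
    "beta0",
    "beta1",
    "V",
    "alpha0",
    "alpha1",
    "alpha2",
    "alpha3",
    "tau",
    "lambda0",
    "lambda1",
    "lambda2",
    "lambda3",
)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws: one row per draw across all chains."""

    globals_: pd.DataFrame  # columns GLOBAL_PARAMS (+ nu2/phi when spatial)
    sigma: np.ndarray  # (n_draws, n_rats)
    delta: np.ndarray
    rho: np.ndarray
    rat_ids: list[str]
    sexes: np.ndarray
    chain: np.ndarray = field(default=None)  # type: ignore[assignment]
    diagnostics: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.globals_)
        if self.chain is None:
            self.chain = np.zeros(n, dtype=int)
        for name, arr in (("sigma", self.sigma), ("delta", self.delta), ("rho", self.rho)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
        if not np.isfinite(self.globals_.to_numpy(dtype=float)).all():
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return len(self.globals_)

    @property
    def n_rats(self) -> int:
        return self.sigma.shape[1]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if self.n_draws else 0

    def mean(self) -> pd.Series:
        return self.globals_.mean()

    def summary(self) -> pd.DataFrame:
        """Posterior mean and central 90% credible interval per parameter."""
        q = self.globals_.quantile([0.05, 0.95])
        return pd.DataFrame(
            {"mean": self.globals_.mean(), "ci5": q.loc[0.05], "ci95": q.loc[0.95]}
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat frame: chain, globals, then sigma/delta/rho per rat."""
        blocks = [pd.DataFrame({"chain": self.chain}), self.globals_]
        for name, arr in (("sigma", self.sigma), ("delta", self.delta), ("rho", self.rho)):
            blocks.append(
                pd.DataFrame(arr, columns=[f"{name}.{r}" for r in self.rat_ids])
            )
        return pd.concat(blocks, axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sexes=None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        rat_ids = [c.split(".", 1)[1] for c in df.columns if c.startswith("sigma.")]
        glob_cols = [c for c in df.columns if c != "chain" and "." not in c]
        return cls(
            globals_=df[glob_cols].copy(),
            sigma=df[[f"sigma.{r}" for r in rat_ids]].to_numpy(),
            delta=df[[f"delta.{r}" for r in rat_ids]].to_numpy(),
            rho=df[[f"rho.{r}" for r in rat_ids]].to_numpy(),
            rat_ids=rat_ids,
            sexes=np.zeros(len(rat_ids), dtype=int) if sexes is None else np.asarray(sexes),
            chain=df["chain"].to_numpy(dtype=int) if "chain" in df else None,
        )
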