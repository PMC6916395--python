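"""Posterior draw container, summaries and convergence diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PosteriorDraws"]


def _rhat_ess(x: np.ndarray) -> tuple[float, float]:
    """Split-Rhat and bulk ESS for one scalar parameter, shape (chain, draw)."""
    import warnings

    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(az.rhat(x)) if x.shape[0] >= 2 else np.nan
        e = float(az.ess(x))
    return r, e


@dataclass
class PosteriorDraws:
    """MCMC output: scalar/array parameter draws plus per-subject random effects.

    ``params`` maps parameter-block names to arrays of shape
    (chains, draws, *block_shape); ``b`` holds the per-subject random-effect
    draws with shape (chains, draws, n_subjects, q).
    """

    params: dict
    b: np.ndarray
    param_names: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one block with chains flattened: (chains*draws, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def stacked_b(self) -> np.ndarray:
        return self.b.reshape(-1, *self.b.shape[2:])

    def _scalar_columns(self):
        """Yield (label, (chains, draws) array) over every scalar component."""
        for name, arr in self.params.items():
            labels = self.param_names.get(name)
            if arr.ndim == 2:
                yield labels[0] if labels else name, arr
            elif arr.ndim == 3:
                for j in range(arr.shape[2]):
                    lab = labels[j] if labels else f"{name}[{j}]"
                    yield lab, arr[:, :, j]
            elif arr.ndim == 4:  # covariance matrices: unique entries
                for j in range(arr.shape[2]):
                    for k in range(j + 1):
                        yield f"{name}[{j},{k}]", arr[:, :, j, k]

    def summary(self, diagnostics: bool = True) -> pd.DataFrame:
        """Posterior summary table: mean, sd, 2.5% / 97.5%, Rhat, ESS."""
        rows = []
        for label, x in self._scalar_columns():
            flat = x.ravel()
            row = {
                "parameter": label,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
            }
            if diagnostics:
                row["rhat"], row["ess"] = _rhat_ess(x)
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    def check_convergence(self, threshold: float = 1.05) -> bool:
        """True if split-Rhat < threshold for every reported parameter."""
        summ = self.summary(diagnostics=True)
        bad = summ[summ["rhat"] >= threshold]  # NaN (single chain) passes
        if len(bad):
            logger.warning(
                "possible non-convergence (Rhat >= %.2f): %s",
                threshold, ", ".join(bad.index.astype(str)),
            )
        return len(bad) == 0

    def credible_interval(self, label: str, level=0.95) -> tuple[float, float]:
        for lab, x in self._scalar_columns():
            if lab == label:
                lo = (1 - level) / 2
                return (float(np.quantile(x, lo)),
                        float(np.quantile(x, 1 - lo)))
        raise KeyError(label)
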