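"""Container for multi-study effect summaries.

The observed data throughout the package is a table of per-study effect
estimates ``beta_hat`` and their standard errors ``se`` — the summary
statistics a meta-analysis or multi-context (e.g. multi-tissue eQTL)
comparison starts from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EffectTable"]


@dataclass(frozen=True)
class EffectTable:
    """Per-study effect estimates with standard errors.

    Parameters
    ----------
    beta_hat
        Estimated effects, one per study, on the analysis scale
        (regression coefficient, log odds ratio, standardized mean
        difference, ...).
    se
        Standard errors of the estimates; strictly positive.
    study
        Study labels. Defaults to ``s1..sm``.
    """

    beta_hat: np.ndarray
    se: np.ndarray
    study: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta_hat, dtype=float)
        se = np.asarray(self.se, dtype=float)
        if beta.ndim != 1 or se.ndim != 1 or beta.shape != se.shape:
            raise ValueError("beta_hat and se must be 1-d arrays of equal length")
        if beta.size < 2:
            raise ValueError(f"at least 2 studies required, got {beta.size}")
        if not (np.isfinite(beta).all() and np.isfinite(se).all()):
            raise ValueError("beta_hat and se must be finite")
        bad = np.flatnonzero(se <= 0)
        if bad.size:
            raise ValueError(f"non-positive standard errors at rows {bad.tolist()}")
        if self.study is None:
            labels = np.array([f"s{i + 1}" for i in range(beta.size)], dtype=object)
        else:
            labels = np.asarray(self.study, dtype=object)
            if labels.shape != beta.shape:
                raise ValueError("study labels must match the number of effects")
        object.__setattr__(self, "beta_hat", beta)
        object.__setattr__(self, "se", se)
        object.__setattr__(self, "study", labels)

    @property
    def m(self) -> int:
        """Number of studies."""
        return int(self.beta_hat.size)

    @property
    def variances(self) -> np.ndarray:
        """Observed sampling variances ``se**2``."""
        return self.se**2

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EffectTable":
        """Build from a DataFrame with columns ``study``, ``beta``, ``se``."""
        missing = {"study", "beta", "se"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        return cls(
            beta_hat=df["beta"].to_numpy(dtype=float),
            se=df["se"].to_numpy(dtype=float),
            study=df["study"].to_numpy(dtype=object),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"study": self.study, "beta": self.beta_hat, "se": self.se}
        )

    def with_effects(self, beta_hat: np.ndarray) -> "EffectTable":
        """A copy with replaced effects and identical standard errors."""
        return EffectTable(beta_hat=np.asarray(beta_hat, float), se=self.se, study=self.study)
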