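"""Phi-correlation screening of every symptom against an index symptom.

The statistic is the phi coefficient: the Pearson product-moment correlation
of two 0/1 indicator vectors, algebraically equal to the normalised 2x2
contingency-table statistic

    phi = (n11 n00 - n10 n01) / sqrt(n1. n0. n.1 n.0).

For each symptom the screen reports, against a chosen index symptom:

* ``r`` — the phi coefficient on ``n`` patients;
* a Fisher-z confidence interval: ``tanh(atanh(r) -/+ q / sqrt(n-3))`` with
  ``q`` the two-sided normal quantile at the confidence level;
* a two-sided p-value from ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` df;
* post-hoc power of the two-sided rho=0 test at size ``alpha``, evaluated at
  the observed effect via the Fisher-z normal approximation;
* an effect-size band under Cohen's conventions (|r| < 0.10 negligible,
  0.10–0.30 small, 0.30–0.50 medium, >= 0.50 large);

and can list the symptoms whose coefficient is zero at the reporting
precision (|r| below a tolerance that rounds to 0.00 at two decimals).

The model object is :class:`SymptomScreen`; :meth:`SymptomScreen.fit`
returns a :class:`ScreenResults` carrying one :class:`CorrelationResult`
per symptom, sorted by descending |r|.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ScreenConfig",
    "ScreenResults",
    "SymptomScreen",
    "phi_correlation",
    "fisher_ci",
    "correlation_p_value",
    "post_hoc_power",
    "cohen_band",
    "screen",
    "independent_set",
]

logger = logging.getLogger(__name__)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used for display tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# -- elementary statistics --------------------------------------------------


def phi_correlation(x: Sequence[int], y: Sequence[int]) -> float:
    """Phi coefficient (Pearson correlation) of two 0/1 vectors.

    Raises
    ------
    ValueError
        If the vectors differ in length, are shorter than 3, or either is
        constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = n - n11 - n10 - n01
    n1_, n0_ = n11 + n10, n01 + n00
    n_1, n_0 = n11 + n01, n10 + n00
    if min(n1_, n0_) == 0:
        raise ValueError("x is constant; phi undefined")
    if min(n_1, n_0) == 0:
        raise ValueError("y is constant; phi undefined")
    return (n11 * n00 - n10 * n01) / math.sqrt(
        float(n1_) * n0_ * n_1 * n_0
    )


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if not -1.0 < r < 1.0:
        raise ValueError("fisher_ci requires |r| < 1")
    if n < 4:
        raise ValueError("fisher_ci requires n >= 4")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return math.tanh(z - q * se), math.tanh(z + q * se)


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for rho=0, exact t reference on n-2 df."""
    if not -1.0 < r < 1.0:
        raise ValueError("correlation_p_value requires |r| < 1")
    if n < 4:
        raise ValueError("correlation_p_value requires n >= 4")
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def post_hoc_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided rho=0 test at size ``alpha``, true effect atanh(r).

    Fisher-z normal approximation:
    ``Phi(|atanh r| sqrt(n-3) - q) + Phi(-|atanh r| sqrt(n-3) - q)``.
    At r=0 this equals alpha exactly.
    """
    if n < 4:
        raise ValueError("post_hoc_power requires n >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if r == 0.0:
        return float(alpha)  # power at the null is the test size, exactly
    q = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = abs(math.atanh(r)) * math.sqrt(n - 3)
    return float(stats.norm.cdf(delta - q) + stats.norm.cdf(-delta - q))


# -- configuration and results ---------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the correlation screen."""

    index_symptom: str = "auditory hallucination"
    ci_level: float = 0.95
    alpha: float = 0.05
    band_low: float = 0.10
    band_high: float = 0.30
    zero_tolerance: float = 0.005
    adjust: str = "none"  # or "benjamini-hochberg"

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.zero_tolerance < self.band_low < self.band_high <= 1.0:
            raise ValueError(
                "require 0 <= zero_tolerance < band_low < band_high <= 1"
            )
        if self.adjust not in {"none", "benjamini-hochberg"}:
            raise ValueError(f"unknown adjust method {self.adjust!r}")


def cohen_band(r: float, config: ScreenConfig = ScreenConfig()) -> str:
    """Effect-size band under Cohen's conventions; lower edges inclusive."""
    a = abs(r)
    if a > 1.0:
        raise ValueError("|r| must be <= 1")
    if a < config.band_low:
        return "negligible"
    if a < config.band_high:
        return "small"
    if a < 0.50:
        return "medium"
    return "large"


@dataclass(frozen=True)
class CorrelationResult:
    """One symptom's association with the index symptom (one results-table row)."""

    symptom: str
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    power: float
    n: int
    band: str
    p_adjusted: float | None = None

    @property
    def df(self) -> int:
        return self.n - 2

    def __post_init__(self) -> None:
        if not self.ci_low <= self.r <= self.ci_high:
            raise ValueError("CI must contain r")
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must be in [0, 1]")


def independent_set(
    results: Sequence[CorrelationResult], config: ScreenConfig = ScreenConfig()
) -> list[str]:
    """Symptoms whose coefficient is zero at the reporting precision.

    With the default tolerance 0.005, exactly those whose r rounds to 0.00
    at two decimals.  Sorted alphabetically.
    """
    return sorted(res.symptom for res in results if abs(res.r) < config.zero_tolerance)


class ScreenResults:
    """Results of a fitted :class:`SymptomScreen`.

    Attributes
    ----------
    results : list[CorrelationResult]
        One entry per screened symptom, sorted by descending |r| (ties
        alphabetical).
    skipped : list[str]
        Constant columns that could not be screened.
    """

    def __init__(
        self,
        results: list[CorrelationResult],
        config: ScreenConfig,
        n: int,
        skipped: list[str],
    ) -> None:
        self.results = results
        self.config = config
        self.n = n
        self.skipped = skipped

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def frame(self) -> pd.DataFrame:
        """Full-precision results table."""
        rows = [
            {
                "symptom": res.symptom,
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "power": res.power,
                "n": res.n,
                "df": res.df,
                "band": res.band,
                **(
                    {"p_adjusted": res.p_adjusted}
                    if res.p_adjusted is not None
                    else {}
                ),
            }
            for res in self.results
        ]
        return pd.DataFrame(rows)

    def display_frame(self) -> pd.DataFrame:
        """Two-decimal display table (p printed as '< 0.0001' when below)."""
        rows = []
        for res in self.results:
            rows.append(
                {
                    "symptom": res.symptom,
                    "R": f"{round_half_away(res.r):.2f}",
                    "CI 95%": f"[{round_half_away(res.ci_low):.2f}, "
                    f"{round_half_away(res.ci_high):.2f}]",
                    "p-value": (
                        "< 0.0001"
                        if res.p_value < 1e-4
                        else f"{res.p_value:.4f}"
                    ),
                    "power": f"{round_half_away(res.power):.2f}".rstrip("0").rstrip("."),
                    "band": res.band,
                }
            )
        return pd.DataFrame(rows)

    def independent_symptoms(self) -> list[str]:
        """The coefficient-0 scan (|r| below the zero tolerance)."""
        return independent_set(self.results, self.config)

    def top_correlates(self) -> list[CorrelationResult]:
        """Results in the small band (both signs), order preserved."""
        return [res for res in self.results if res.band == "small"]

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Symptom correlation screen",
            "=" * 26,
            f"index symptom : {self.config.index_symptom}",
            f"n patients    : {self.n}   (df = {self.n - 2})",
            f"CI level      : {self.config.ci_level:g}   alpha: {self.config.alpha:g}",
            f"screened      : {len(self.results)} symptoms"
            + (f"   skipped (constant): {len(self.skipped)}" if self.skipped else ""),
            "",
            self.display_frame().to_string(index=False),
            "",
            f"independent (|r| < {self.config.zero_tolerance:g}): "
            f"{len(self.independent_symptoms())} symptoms",
        ]
        return "\n".join(lines)

    def save(self, path, header_lines: Sequence[str] = ()) -> None:
        """Write the full-precision table as delimited text."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, index=False, lineterminator="\n")


class SymptomScreen:
    """Model: phi-correlation screen of a binary matrix against an index symptom.

    Parameters
    ----------
    matrix
        Patient x symptom binary DataFrame (cleaned analysis dataset).
    config
        :class:`ScreenConfig`; keyword overrides (``index_symptom=...`` etc.)
        are applied on top.

    Examples
    --------
    >>> model = SymptomScreen(matrix, index_symptom="auditory hallucination")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self, matrix: pd.DataFrame, config: ScreenConfig | None = None, **overrides
    ) -> None:
        self.matrix = matrix
        self.config = replace(config or ScreenConfig(), **overrides)

    @classmethod
    def from_corpus(
        cls,
        records,
        lexicon,
        config: ScreenConfig | None = None,
        **overrides,
    ) -> "SymptomScreen":
        """Build the model straight from narratives: extract, encode, clean."""
        from .encoding import build_matrix, clean_matrix
        from .extraction import extract_corpus

        sets = extract_corpus(records, lexicon)
        matrix = build_matrix(sets, lexicon)
        cleaned, report = clean_matrix(matrix, lexicon, raw_records=records)
        model = cls(cleaned, config, **overrides)
        model.cleaning_report = report
        return model

    def fit(self) -> ScreenResults:
        cfg = self.config
        index = cfg.index_symptom
        if index not in self.matrix.columns:
            raise ValueError(f"index symptom {index!r} not in matrix columns")
        y = self.matrix[index].to_numpy()
        n = len(y)
        if len(set(y.tolist())) < 2:
            raise ValueError(f"index symptom {index!r} is constant")

        results: list[CorrelationResult] = []
        skipped: list[str] = []
        for col in self.matrix.columns:
            if col == index:
                continue
            x = self.matrix[col].to_numpy()
            try:
                r = phi_correlation(x, y)
            except ValueError:
                skipped.append(col)
                warnings.warn(
                    f"column {col!r} is constant; skipped in screen", stacklevel=2
                )
                continue
            if abs(r) == 1.0:
                # degenerate: the column duplicates (or mirrors) the index
                lo, hi, p, pw = r, r, 0.0, 1.0
            elif n < 4:
                # too few rows for a Fisher-z interval; CI is uninformative
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                lo, hi = -1.0, 1.0
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
                pw = cfg.alpha
            else:
                lo, hi = fisher_ci(r, n, cfg.ci_level)
                p = correlation_p_value(r, n)
                pw = post_hoc_power(r, n, cfg.alpha)
            results.append(
                CorrelationResult(
                    symptom=col,
                    r=r,
                    ci_low=lo,
                    ci_high=hi,
                    p_value=p,
                    power=pw,
                    n=n,
                    band=cohen_band(r, cfg),
                )
            )
        results.sort(key=lambda res: (-abs(res.r), res.symptom))
        if cfg.adjust == "benjamini-hochberg" and results:
            from statsmodels.stats.multitest import multipletests

            _, p_adj, _, _ = multipletests(
                [res.p_value for res in results], method="fdr_bh"
            )
            results = [
                replace(res, p_adjusted=float(p)) for res, p in zip(results, p_adj)
            ]
        return ScreenResults(results, cfg, n, skipped)


def screen(
    matrix: pd.DataFrame, config: ScreenConfig = ScreenConfig()
) -> list[CorrelationResult]:
    """Functional wrapper: fit a :class:`SymptomScreen` and return its result rows."""
    return SymptomScreen(matrix, config).fit().results
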