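"""Synthetic narrative corpora with known symptom prevalences and pairwise phi.

Correlated binary symptom indicators are generated with a latent-threshold
(Gaussian copula) construction: each symptom ``j`` is 1 when a standard
normal latent variable exceeds the upper-tail quantile of its prevalence,
and a target phi for a pair is hit by solving, with monotone root finding
on the bivariate-normal orthant probability, for the latent correlation
whose thresholded 2x2 table has exactly that phi.  Pairs without a target
are generated independent; an infeasible (non-PSD) joint target set fails
loudly unless nearest-PSD repair is explicitly requested.

Narratives are rendered from the binary rows: every present symptom
appears as ``1 + Poisson(repeat_mention_rate)`` mentions, each mention a
uniformly chosen surface form from the lexicon, with filler (non-symptom)
words interleaved between mentions.  Because the filler vocabulary is
disjoint from every surface-form token and at least one filler separates
consecutive mentions, extraction recovers the generated row exactly —
the round trip render -> extract -> encode is lossless by construction.

The default profile mirrors a web-scraped mental-health corpus: 10,933 raw
records of which 704 contain no symptom mention and 1 is an exact duplicate
(so cleaning leaves 10,228), a low-prevalence index symptom (~5.7% of raw
records), a handful of planted small correlations with the index, and a
block of symptoms exactly independent of it.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .extraction import NarrativeRecord
from .lexicon import SymptomLexicon, demo_lexicon

__all__ = [
    "GeneratorConfig",
    "CorpusProfile",
    "LatentModel",
    "feasible_phi_bounds",
    "phi_from_latent",
    "phi_to_latent_correlation",
    "build_latent_model",
    "sample_binary_matrix",
    "render_narratives",
    "simulate_corpus",
    "default_profile",
    "DEFAULT_FILLERS",
]

logger = logging.getLogger(__name__)

#: Filler (non-symptom) words; deliberately disjoint from every token of every
#: surface form in the demonstration lexicon so rendering can never create a
#: spurious symptom mention.
DEFAULT_FILLERS = (
    "i", "me", "my", "was", "is", "it", "a", "to", "been", "being",
    "do", "dont", "cant", "had", "has", "every", "day", "really", "so",
    "much", "went", "doctor", "started", "medication", "better", "now",
    "life", "home", "work", "people", "think", "about", "never", "still",
    "today", "morning", "nothing", "anything", "everything", "sometimes",
    "because", "wanted", "trying", "getting", "would", "could", "again",
)


def _phi_from_cells(p11: float, p1: float, p2: float) -> float:
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return (p11 - p1 * p2) / denom


def feasible_phi_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Attainable phi range for two binaries with the given marginals.

    The Frechet bounds on the joint cell ``P11`` — ``max(0, p1+p2-1)`` below
    and ``min(p1, p2)`` above — translate directly into bounds on phi.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("prevalences must be strictly inside (0, 1)")
    lo = _phi_from_cells(max(0.0, p1 + p2 - 1.0), p1, p2)
    hi = _phi_from_cells(min(p1, p2), p1, p2)
    return lo, hi


def _upper_orthant(t1: float, t2: float, rho: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation rho."""
    if abs(rho) < 1e-14:
        return float(stats.norm.sf(t1) * stats.norm.sf(t2))
    if rho > 1 - 1e-12:
        return float(stats.norm.sf(max(t1, t2)))
    if rho < -1 + 1e-12:
        return float(max(0.0, stats.norm.cdf(-t2) - stats.norm.cdf(t1)))
    s = math.sqrt(1.0 - rho * rho)

    def integrand(z: float) -> float:
        return stats.norm.pdf(z) * stats.norm.sf((t2 - rho * z) / s)

    val, _ = integrate.quad(integrand, t1, np.inf, epsabs=1e-12, epsrel=1e-10)
    return float(val)


def phi_from_latent(p1: float, p2: float, rho: float) -> float:
    """Phi of the 2x2 table from thresholding a bivariate normal at the margins."""
    t1 = stats.norm.isf(p1)
    t2 = stats.norm.isf(p2)
    return _phi_from_cells(_upper_orthant(t1, t2, rho), p1, p2)


def phi_to_latent_correlation(p1: float, p2: float, phi: float) -> float:
    """Latent correlation whose thresholded table has the target phi.

    Solved to ~1e-9 by Brent root finding; phi is monotone increasing in the
    latent correlation for fixed margins.  phi=0 maps to 0 exactly.
    """
    lo, hi = feasible_phi_bounds(p1, p2)
    if not lo < phi < hi:
        raise ValueError(
            f"phi={phi:g} infeasible for margins ({p1:g}, {p2:g}); "
            f"attainable range is ({lo:.6f}, {hi:.6f})"
        )
    if phi == 0.0:
        return 0.0
    f = lambda rho: phi_from_latent(p1, p2, rho) - phi
    return float(optimize.brentq(f, -1 + 1e-10, 1 - 1e-10, xtol=1e-12, rtol=1e-14))


# -- configuration ----------------------------------------------------------


def _pair_key(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"phi target for a symptom with itself: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters for one synthetic corpus.

    Use :meth:`create` to build from plain dicts; fields are stored as
    sorted tuples so configs are hashable (latent solves are cached).
    """

    n_patients: int
    prevalences: tuple[tuple[str, float], ...]
    phi_targets: tuple[tuple[str, str, float], ...] = ()
    filler_vocabulary: tuple[str, ...] = DEFAULT_FILLERS
    repeat_mention_rate: float = 0.5
    seed: int = 0

    @classmethod
    def create(
        cls,
        n_patients: int,
        prevalences: Mapping[str, float],
        phi_targets: Mapping[tuple[str, str], float] | None = None,
        **kwargs,
    ) -> "GeneratorConfig":
        targets = tuple(
            sorted(
                (*_pair_key(a, b), float(phi))
                for (a, b), phi in (phi_targets or {}).items()
            )
        )
        return cls(
            n_patients=n_patients,
            prevalences=tuple(sorted((s, float(p)) for s, p in prevalences.items())),
            phi_targets=targets,
            **kwargs,
        )

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.repeat_mention_rate < 0:
            raise ValueError("repeat_mention_rate must be non-negative")
        prev = dict(self.prevalences)
        for s, p in prev.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {s!r} must be in (0, 1), got {p}")
        for a, b, phi in self.phi_targets:
            for s in (a, b):
                if s not in prev:
                    raise ValueError(f"phi target names unknown symptom {s!r}")
            lo, hi = feasible_phi_bounds(prev[a], prev[b])
            if phi != 0.0 and not lo < phi < hi:
                raise ValueError(
                    f"phi target {phi:g} for ({a!r}, {b!r}) outside feasible "
                    f"range ({lo:.6f}, {hi:.6f})"
                )

    @property
    def prevalence_map(self) -> dict[str, float]:
        return dict(self.prevalences)

    @property
    def phi_map(self) -> dict[tuple[str, str], float]:
        return {(a, b): phi for a, b, phi in self.phi_targets}

    @property
    def symptoms(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.prevalences)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class LatentModel:
    """Thresholds and latent correlation matrix implied by a config."""

    symptoms: tuple[str, ...]
    thresholds: np.ndarray  # upper-tail prevalence quantiles
    latent_correlations: np.ndarray  # full correlation matrix

    def factor(self) -> np.ndarray:
        """A matrix L with L L' = latent_correlations (Cholesky or eigh)."""
        try:
            return np.linalg.cholesky(self.latent_correlations)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(self.latent_correlations)
            return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@lru_cache(maxsize=64)
def _latent_pieces(
    prevalences: tuple[tuple[str, float], ...],
    phi_targets: tuple[tuple[str, str, float], ...],
    nearest_psd: bool,
) -> LatentModel:
    symptoms = tuple(s for s, _ in prevalences)
    prev = dict(prevalences)
    k = len(symptoms)
    idx = {s: j for j, s in enumerate(symptoms)}
    corr = np.eye(k)
    for a, b, phi in phi_targets:
        rho = phi_to_latent_correlation(prev[a], prev[b], phi)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    eigmin = float(np.linalg.eigvalsh(corr).min()) if k else 0.0
    if eigmin < -1e-10:
        if not nearest_psd:
            pairs = [(a, b) for a, b, _ in phi_targets]
            raise ValueError(
                f"joint phi targets are infeasible: latent correlation matrix "
                f"has minimum eigenvalue {eigmin:.3e} (< 0); offending target "
                f"pairs: {pairs}. Pass nearest_psd=True to clip eigenvalues."
            )
        warnings.warn(
            f"latent correlation matrix not PSD (min eigenvalue {eigmin:.3e}); "
            "applying nearest-PSD eigenvalue clipping — empirical phi will "
            "deviate from the targets",
            stacklevel=2,
        )
        w, v = np.linalg.eigh(corr)
        corr = v @ np.diag(np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    thresholds = stats.norm.isf([prev[s] for s in symptoms])
    return LatentModel(symptoms, thresholds, corr)


def build_latent_model(
    config: GeneratorConfig, nearest_psd: bool = False
) -> LatentModel:
    """Solve every pairwise phi target into the joint latent-threshold model."""
    return _latent_pieces(config.prevalences, config.phi_targets, nearest_psd)


# -- sampling ---------------------------------------------------------------


def sample_binary_matrix(
    config: GeneratorConfig,
    nearest_psd: bool = False,
    rng: np.random.Generator | None = None,
    n: int | None = None,
) -> pd.DataFrame:
    """Sample the ground-truth patient x symptom binary matrix.

    Deterministic given ``config.seed``; pairs without a phi target are
    independent.
    """
    model = build_latent_model(config, nearest_psd)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients if n is None else n
    L = model.factor()
    z = rng.standard_normal((n, len(model.symptoms))) @ L.T
    cells = (z > model.thresholds).astype(np.int8)
    ids = [f"P{i + 1:06d}" for i in range(n)]
    return pd.DataFrame(
        cells, index=pd.Index(ids, name="patient_id"), columns=list(model.symptoms)
    )


def _render_row(
    present: list[str],
    lexicon: SymptomLexicon,
    config: GeneratorConfig,
    rng: np.random.Generator,
    min_fillers_if_empty: int = 3,
) -> str:
    fillers = config.filler_vocabulary
    tokens: list[str] = []

    def filler_run(k: int) -> None:
        if k > 0 and fillers:
            tokens.extend(rng.choice(fillers, size=k))

    mentions: list[str] = []
    for symptom in present:
        forms = lexicon.entries[symptom]
        count = 1 + rng.poisson(config.repeat_mention_rate)
        for _ in range(count):
            mentions.append(forms[rng.integers(len(forms))])
    rng.shuffle(mentions)
    if not mentions:
        filler_run(min_fillers_if_empty + rng.poisson(8))
        return " ".join(tokens)
    filler_run(rng.poisson(3))
    for mention in mentions:
        tokens.extend(mention.split())
        filler_run(1 + rng.poisson(2))  # >=1 filler: mentions never touch
    return " ".join(tokens)


def render_narratives(
    matrix: pd.DataFrame,
    lexicon: SymptomLexicon,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[NarrativeRecord]:
    """Render each binary row into a narrative whose extraction recovers the row.

    Every present symptom appears as at least one surface form; absent
    symptoms never appear; filler words are interleaved.  Deterministic
    given ``config.seed``.
    """
    unknown = set(matrix.columns) - set(lexicon.canonicals)
    if unknown:
        raise ValueError(f"matrix columns not in lexicon: {sorted(unknown)}")
    bad = set(config.filler_vocabulary) & lexicon.surface_tokens
    if bad:
        raise ValueError(
            f"filler words collide with lexicon surface-form tokens: {sorted(bad)}"
        )
    if rng is None:
        rng = np.random.default_rng([1, config.seed])
    columns = np.asarray(matrix.columns)
    records = []
    for pid, row in zip(matrix.index, matrix.to_numpy()):
        present = [str(s) for s in columns[row == 1]]
        records.append(NarrativeRecord(str(pid), _render_row(present, lexicon, config, rng)))
    return records


# -- corpus-level simulation ------------------------------------------------


@dataclass(frozen=True)
class CorpusProfile:
    """Raw-corpus shape: how many zero-symptom records and duplicates to inject."""

    n_zero_symptom: int = 0
    n_duplicates: int = 0


def simulate_corpus(
    config: GeneratorConfig,
    lexicon: SymptomLexicon,
    profile: CorpusProfile = CorpusProfile(),
    nearest_psd: bool = False,
) -> tuple[list[NarrativeRecord], pd.DataFrame, dict]:
    """Generate a full raw corpus: narratives, ground-truth matrix, manifest.

    ``config.n_patients`` is the total raw record count.  Of these,
    ``profile.n_zero_symptom`` records carry no symptom at all and
    ``profile.n_duplicates`` are exact text copies of earlier records, so
    downstream cleaning leaves exactly
    ``n_patients - n_zero_symptom - n_duplicates`` rows.  Non-zero rows are
    drawn from the latent-threshold model conditioned on being non-zero
    (all-zero draws are rejected and redrawn).
    """
    n_total = config.n_patients
    n_core = n_total - profile.n_zero_symptom - profile.n_duplicates
    if n_core < 0:
        raise ValueError("profile removes more rows than the corpus has")
    if profile.n_duplicates > 0 and n_core == 0:
        raise ValueError("cannot inject duplicates into an empty core")

    rng = np.random.default_rng(config.seed)
    model = build_latent_model(config, nearest_psd)
    L = model.factor()
    k = len(model.symptoms)

    rows: list[np.ndarray] = []
    while len(rows) < n_core:
        batch = max(256, int(1.2 * (n_core - len(rows))))
        z = rng.standard_normal((batch, k)) @ L.T
        cells = (z > model.thresholds).astype(np.int8)
        rows.extend(cells[cells.sum(axis=1) > 0])
    core = np.array(rows[:n_core], dtype=np.int8).reshape(n_core, k)

    zero_block = np.zeros((profile.n_zero_symptom, k), dtype=np.int8)
    dup_sources = (
        rng.integers(n_core, size=profile.n_duplicates)
        if profile.n_duplicates
        else np.empty(0, dtype=int)
    )
    full = np.vstack([core, zero_block, core[dup_sources]])

    bad = set(config.filler_vocabulary) & lexicon.surface_tokens
    if bad:
        raise ValueError(
            f"filler words collide with lexicon surface-form tokens: {sorted(bad)}"
        )
    columns = list(model.symptoms)
    render_rng = np.random.default_rng([1, config.seed])
    n_unique = n_core + profile.n_zero_symptom
    texts = [
        _render_row(
            [s for s, cell in zip(columns, full[i]) if cell], lexicon, config,
            render_rng,
        )
        for i in range(n_unique)
    ]
    texts.extend(texts[s] for s in dup_sources)  # duplicates: identical text

    order = rng.permutation(n_total)
    ids = [f"P{i + 1:06d}" for i in range(n_total)]
    matrix = pd.DataFrame(
        full[order], index=pd.Index(ids, name="patient_id"), columns=columns
    )
    records = [NarrativeRecord(ids[pos], texts[order[pos]]) for pos in range(n_total)]

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": n_total,
        "n_zero_symptom": int(profile.n_zero_symptom),
        "n_duplicates": int(profile.n_duplicates),
        "n_symptoms": k,
        "expected_rows_after_cleaning": n_core,
    }
    logger.info("simulated corpus: %s", manifest)
    return records, matrix, manifest


# -- the default, study-shaped profile --------------------------------------

#: Marginal prevalences among symptom-bearing (non-zero) records.  The index
#: symptom sits near 6.1% of non-zero records, i.e. ~5.7% of the raw corpus
#: once the zero-symptom records are counted in.
DEFAULT_PREVALENCES: dict[str, float] = {
    "auditory hallucination": 0.061,
    "visual hallucination": 0.05,
    "schizophrenia": 0.09,
    "fear": 0.35,
    "delusion": 0.08,
    "psychosis": 0.07,
    "paranoia": 0.10,
    "suicide": 0.15,
    "pain": 0.22,
    "trauma": 0.22,
    "depression": 0.55,
    "anxiety": 0.50,
    "loneliness": 0.30,
    "low mood": 0.26,
    "lethargy": 0.15,
    "lack of sleep": 0.25,
    "panic attacks": 0.14,
    "dissociation": 0.05,
    "obsession": 0.06,
    "compulsion": 0.05,
    "hypertension": 0.02,
    "nausea": 0.03,
    "weight loss": 0.03,
    "head": 0.10,
    "sadness": 0.20,
    "apprehensions": 0.08,
    "anger": 0.18,
    "stress": 0.24,
}

#: Planted phi of each correlate with the index symptom (small effects, the
#: strongest 0.26); "head" is planted between the 2nd and 3rd strongest.
DEFAULT_INDEX_PHI: dict[str, float] = {
    "visual hallucination": 0.26,
    "schizophrenia": 0.17,
    "head": 0.16,
    "fear": 0.15,
    "delusion": 0.14,
    "psychosis": 0.14,
    "paranoia": 0.13,
    "suicide": 0.11,
    "pain": 0.11,
    "trauma": 0.10,
}

#: Symptoms planted exactly independent of the index symptom.
DEFAULT_INDEPENDENT: tuple[str, ...] = (
    "dissociation",
    "obsession",
    "compulsion",
    "hypertension",
    "nausea",
    "weight loss",
)

DEFAULT_INDEX = "auditory hallucination"


@lru_cache(maxsize=8)
def _one_factor_targets(
    index: str,
    prevalences: tuple[tuple[str, float], ...],
    index_phi: tuple[tuple[str, float], ...],
    independent: tuple[str, ...],
) -> tuple[tuple[str, str, float], ...]:
    """Fill correlate-correlate pairs with a single-factor latent structure.

    With the index variable's latent as the common factor, the latent
    correlation between two correlates is the product of their latent
    correlations with the index (rho_jk = rho_ij * rho_ik), which keeps the
    joint latent matrix positive semidefinite for any admissible loadings.
    Each implied latent value is converted back to the phi it induces so the
    whole ground truth remains expressed in phi.
    """
    prev = dict(prevalences)
    rho_with_index = {
        s: phi_to_latent_correlation(prev[index], prev[s], phi)
        for s, phi in index_phi
    }
    targets: dict[tuple[str, str], float] = {}
    for s, phi in index_phi:
        targets[_pair_key(index, s)] = phi
    correlates = [s for s, _ in index_phi]
    for i, a in enumerate(correlates):
        for b in correlates[i + 1 :]:
            rho = rho_with_index[a] * rho_with_index[b]
            targets[_pair_key(a, b)] = phi_from_latent(prev[a], prev[b], rho)
    for s in independent:
        targets[_pair_key(index, s)] = 0.0
    return tuple(sorted((*k, v) for k, v in targets.items()))


def default_profile(
    seed: int = 0,
    n_patients: int = 10_933,
    lexicon: SymptomLexicon | None = None,
) -> tuple[GeneratorConfig, CorpusProfile, SymptomLexicon]:
    """The study-shaped corpus: 10,933 raw records, 704 zero-symptom, 1 duplicate."""
    lexicon = lexicon or demo_lexicon()
    targets = _one_factor_targets(
        DEFAULT_INDEX,
        tuple(sorted(DEFAULT_PREVALENCES.items())),
        tuple(sorted(DEFAULT_INDEX_PHI.items())),
        DEFAULT_INDEPENDENT,
    )
    config = GeneratorConfig(
        n_patients=n_patients,
        prevalences=tuple(sorted(DEFAULT_PREVALENCES.items())),
        phi_targets=targets,
        seed=seed,
    )
    scale = n_patients / 10_933
    profile = CorpusProfile(
        n_zero_symptom=int(round(704 * scale)),
        n_duplicates=1 if n_patients >= 3 else 0,
    )
    return config, profile, lexicon
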