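"""Mutational-signature refitting: non-negative exposures over a reference
signature matrix, with the contributing subset chosen by BIC.

A reference matrix gives, for each signature, a probability distribution over
the 96 trinucleotide channels.  An observed spectrum ``s`` is modelled as
``s ≈ M_S · e`` with non-negative exposures ``e`` (mutation counts attributed
to each signature in the subset ``S``).  Exposures are fitted by non-negative
least squares; candidate subsets of growing size are compared with the
Bayesian Information Criterion to avoid over-fitting, and the reconstruction
is scored against the observed spectrum by cosine similarity.

Two BIC forms are offered.  The default treats the 96 channel counts as the
observations of a Gaussian linear model, ``BIC = n·ln(RSS/n) + (k+1)·ln(n)``
with ``n = 96``.  The alternative ``multinomial`` form treats each mutation
as an observation from the mixed channel distribution,
``BIC = -2·lnL + k·ln(N)`` with ``N`` the mutation total; its magnitude
scales with the mutation count rather than the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import DecompositionError
from .spectrum import CHANNEL_LABELS, SNV_CLASSES, Spectrum96

_EPS = 1e-12


@dataclass
class ReferenceSignatures:
    """A 96 x K column-stochastic signature matrix with labels."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError(f"matrix must be 96 x K, got {self.matrix.shape}")
        if len(self.ids) != self.matrix.shape[1]:
            raise ValueError("one id per signature column required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate signature ids")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("every signature column must sum to 1 (within 1e-6)")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def columns(self, subset: Sequence[str]) -> np.ndarray:
        idx = [self.ids.index(s) for s in subset]
        return self.matrix[:, idx]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceSignatures":
        """Read a COSMIC-v2-layout TSV: first column "A[C>A]A"-style context
        labels, remaining columns signatures.  Rows are reordered to the
        canonical channel order."""
        df = pd.read_csv(path, sep="\t")
        labels = df.iloc[:, 0].astype(str)
        df = df.set_index(labels).iloc[:, 1:]
        missing = set(CHANNEL_LABELS) - set(df.index)
        if missing:
            raise ValueError(f"signature matrix missing channels, e.g. {sorted(missing)[:3]}")
        df = df.loc[list(CHANNEL_LABELS)]
        return cls(ids=list(df.columns), matrix=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.ids)
        df.insert(0, "MutationType", CHANNEL_LABELS)
        df.to_csv(path, sep="\t", index=False)


def toy_signatures() -> ReferenceSignatures:
    """A built-in synthetic reference of five well-separated signatures.

    Each signature concentrates most of its mass on one substitution class
    (S1: C>T, S2: C>A, S3: T>C, S4: C>G with a T>G shoulder, S5: flat),
    spread across the 16 contexts of a class by a fixed Dirichlet draw.
    Intended for tests and synthetic cohorts; not derived from any catalogue.
    """
    rng = np.random.default_rng(987654321)
    class_weights = {
        "S1": {"C>T": 0.70, "C>A": 0.06, "C>G": 0.06, "T>A": 0.06, "T>C": 0.06, "T>G": 0.06},
        "S2": {"C>A": 0.70, "C>T": 0.06, "C>G": 0.06, "T>A": 0.06, "T>C": 0.06, "T>G": 0.06},
        "S3": {"T>C": 0.70, "C>A": 0.06, "C>G": 0.06, "C>T": 0.06, "T>A": 0.06, "T>G": 0.06},
        "S4": {"C>G": 0.55, "T>G": 0.15, "C>A": 0.075, "C>T": 0.075, "T>A": 0.075, "T>C": 0.075},
        "S5": {cls: 1.0 / 6.0 for cls in SNV_CLASSES},
    }
    cols = []
    for sig in sorted(class_weights):
        col = np.empty(96)
        for i, cls in enumerate(SNV_CLASSES):
            within = rng.dirichlet(np.full(16, 2.0))
            col[i * 16 : (i + 1) * 16] = class_weights[sig][cls] * within
        cols.append(col / col.sum())
    return ReferenceSignatures(ids=sorted(class_weights), matrix=np.column_stack(cols))


def _as_vector(spectrum: Spectrum96 | np.ndarray) -> np.ndarray:
    if isinstance(spectrum, Spectrum96):
        return spectrum.counts.astype(float)
    arr = np.asarray(spectrum, dtype=float)
    if arr.shape != (96,):
        raise ValueError("spectrum vector must have 96 entries")
    return arr


def nnls_exposures(
    spectrum: Spectrum96 | np.ndarray,
    signatures: ReferenceSignatures,
    subset: Sequence[str],
) -> tuple[np.ndarray, float]:
    """Non-negative least-squares exposures for a signature subset.

    Returns ``(exposures, rss)`` where exposures minimize
    ``||s - M·e||^2`` subject to ``e >= 0`` and ``rss`` is the residual sum
    of squares at the optimum.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise ValueError(f"duplicate ids in subset: {list(subset)}")
    s = _as_vector(spectrum)
    m = signatures.columns(subset)
    exposures, rnorm = scipy.optimize.nnls(m, s)
    return exposures, float(rnorm**2)


def bic_score(rss: float, n_channels: int = 96, k: int = 1) -> float:
    """Gaussian linear-model BIC on the channel counts.

    ``n·ln(max(rss, eps)/n) + (k+1)·ln(n)`` with ``n = n_channels``; the
    ``+1`` counts the residual variance as a fitted parameter.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = n_channels
    return n * np.log(max(rss, _EPS) / n) + (k + 1) * np.log(n)


def multinomial_bic(
    spectrum: Spectrum96 | np.ndarray, reconstruction: np.ndarray, k: int
) -> float:
    """BIC with a multinomial likelihood over individual mutations.

    The reconstruction is normalized to a channel distribution ``p``;
    ``BIC = -2·sum_i s_i·ln(p_i) + k·ln(N)`` with ``N = sum_i s_i``.
    """
    s = _as_vector(spectrum)
    total = s.sum()
    if total <= 0:
        raise DecompositionError("multinomial BIC undefined for an empty spectrum")
    p = np.maximum(np.asarray(reconstruction, dtype=float), 0.0)
    p = np.maximum(p / max(p.sum(), _EPS), _EPS)
    loglik = float(np.sum(s * np.log(p)))
    return -2.0 * loglik + k * np.log(total)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class Decomposition:
    """Result of a BIC-guided signature refit."""

    selected: list[str]
    exposures: np.ndarray
    reconstruction: np.ndarray
    rss: float
    cosine: float
    bic: float
    trace: list[dict] = field(default_factory=list)

    @property
    def exposure_fractions(self) -> np.ndarray:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else self.exposures

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "exposures": [float(e) for e in self.exposures],
            "rss": self.rss,
            "cosine": self.cosine,
            "bic": self.bic,
            "trace": self.trace,
        }


def forward_select(
    spectrum: Spectrum96 | np.ndarray,
    signatures: ReferenceSignatures,
    max_k: int = 10,
    bic_mode: str = "gaussian",
) -> Decomposition:
    """Greedy forward signature selection by BIC.

    Starting from the empty set, each step adds the signature whose addition
    yields the lowest BIC (ties broken by signature id order); the search
    stops when no addition lowers the BIC or ``max_k`` is reached.  The
    returned trace records the candidate chosen and BIC at each step.
    """
    s = _as_vector(spectrum)
    if s.sum() <= 0:
        raise DecompositionError("cannot decompose an all-zero spectrum")
    if not 1 <= max_k <= signatures.k:
        raise ValueError(f"max_k must be in [1, {signatures.k}], got {max_k}")
    if bic_mode not in ("gaussian", "multinomial"):
        raise ValueError(f"unknown bic_mode {bic_mode!r}")

    def score(subset: list[str]) -> tuple[np.ndarray, float, float]:
        exp, rss = nnls_exposures(s, signatures, subset)
        recon = signatures.columns(subset) @ exp
        if bic_mode == "gaussian":
            bic = bic_score(rss, 96, len(subset))
        else:
            bic = multinomial_bic(s, recon, len(subset))
        return exp, rss, bic

    selected: list[str] = []
    best: Decomposition | None = None
    trace: list[dict] = []
    while len(selected) < max_k:
        candidates = sorted(set(signatures.ids) - set(selected))
        step_best: tuple[float, str, np.ndarray, float] | None = None
        for sig in candidates:  # sorted: lexical tie-break via strict <
            exp, rss, bic = score(selected + [sig])
            if step_best is None or bic < step_best[0]:
                step_best = (bic, sig, exp, rss)
        assert step_best is not None
        bic, sig, exp, rss = step_best
        if best is not None and bic >= best.bic:
            break
        selected = selected + [sig]
        recon = signatures.columns(selected) @ exp
        best = Decomposition(
            selected=list(selected),
            exposures=exp,
            reconstruction=recon,
            rss=rss,
            cosine=cosine_similarity(s, recon),
            bic=bic,
        )
        trace.append({"added": sig, "k": len(selected), "bic": float(bic), "rss": float(rss)})
    assert best is not None
    best.trace = trace
    return best
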