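"""Dual-retrieval model of repeated free recall.

The model explains an item's correct (C) / error (E) outcomes across three
successive recall tests through three latent routes:

* **Direct access** — with probability ``D`` the item's verbatim trace is
  directly accessible at test 1 and the item is recalled with certainty.
  After each test the trace survives the inter-test interval with
  probability ``1 - F``; once lost it is unrecallable on all later tests.
* **Reconstruction** — with probability ``(1 - D) * R`` the item can be
  reconstructed from gist (e.g., its taxonomic category).  A reconstructed
  item is output on test *t* independently with the familiarity-judgment
  probability ``J_t``.
* **Neither** — with probability ``(1 - D) * (1 - R)`` the item is never
  recalled.

This yields a multinomial distribution over the 8 three-test patterns with
6 free parameters, leaving 8 - 1 - 6 = 1 residual degree of freedom for a
goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PATTERN_LABELS",
    "DualRetrievalParams",
    "PatternDistribution",
    "PatternCounts",
    "pattern_index",
    "pattern_label",
    "pattern_probabilities",
    "simulate_patterns",
]

#: Parameter order used for arrays, optimization vectors and text records.
PARAM_NAMES: tuple[str, ...] = ("D", "F", "J1", "J2", "J3", "R")

#: Pattern labels by canonical index: index = 4*[t1=C] + 2*[t2=C] + [t3=C].
PATTERN_LABELS: tuple[str, ...] = (
    "EEE", "EEC", "ECE", "ECC", "CEE", "CEC", "CCE", "CCC",
)

_FIELD_BY_NAME = {
    "D": "direct_access",
    "F": "forgetting",
    "J1": "familiarity_t1",
    "J2": "familiarity_t2",
    "J3": "familiarity_t3",
    "R": "reconstruction",
}


def pattern_index(t1: bool, t2: bool, t3: bool) -> int:
    """Canonical index of a recall pattern (test 1 = most significant bit)."""
    return 4 * int(t1) + 2 * int(t2) + int(t3)


def pattern_label(index: int) -> str:
    return PATTERN_LABELS[index]


@dataclass(frozen=True)
class DualRetrievalParams:
    """The six latent-process probabilities of the dual-retrieval model.

    Parameters
    ----------
    direct_access : float
        ``D`` — probability that verbatim traces are directly accessible on
        the first recall test.
    forgetting : float
        ``F`` — probability that direct access is lost after the first or
        second recall test (one rate shared by both inter-test intervals).
    reconstruction : float
        ``R`` — probability that, when direct access fails, the item can be
        reconstructed from gist traces.
    familiarity_t1, familiarity_t2, familiarity_t3 : float
        ``J1``, ``J2``, ``J3`` — probability that a reconstructed item is
        judged familiar enough to output on tests 1-3.
    """

    direct_access: float
    forgetting: float
    reconstruction: float
    familiarity_t1: float
    familiarity_t2: float
    familiarity_t3: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"parameter {f.name!r} must lie in [0, 1], got {v!r}"
                )

    def to_array(self) -> np.ndarray:
        """Parameter vector in the canonical (D, F, J1, J2, J3, R) order."""
        return np.array([getattr(self, _FIELD_BY_NAME[n]) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, values) -> "DualRetrievalParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError(f"expected 6 parameter values, got shape {values.shape}")
        kwargs = {_FIELD_BY_NAME[n]: float(v) for n, v in zip(PARAM_NAMES, values)}
        return cls(**kwargs)

    def to_record(self) -> str:
        """Two-line delimited text record with header ``D,F,J1,J2,J3,R``."""
        header = ",".join(PARAM_NAMES)
        body = ",".join(repr(float(v)) for v in self.to_array())
        return f"{header}\n{body}\n"

    @classmethod
    def from_record(cls, text: str) -> "DualRetrievalParams":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if len(lines) != 2 or [c.strip() for c in lines[0].split(",")] != list(PARAM_NAMES):
            raise ValueError("expected a header line 'D,F,J1,J2,J3,R' and one value line")
        return cls.from_array([float(v) for v in lines[1].split(",")])


@dataclass(frozen=True)
class PatternDistribution:
    """Probabilities of the 8 three-test recall patterns, canonical order."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (8,):
            raise ValueError("pattern distribution needs exactly 8 probabilities")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("pattern probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"pattern probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "probabilities", p)

    def __getitem__(self, label_or_index) -> float:
        if isinstance(label_or_index, str):
            return float(self.probabilities[PATTERN_LABELS.index(label_or_index)])
        return float(self.probabilities[label_or_index])


@dataclass(frozen=True)
class PatternCounts:
    """Observed frequencies of the 8 recall patterns for one condition."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (8,):
            raise ValueError("pattern counts need exactly 8 cells")
        if np.any(c < 0):
            raise ValueError("pattern counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, label_or_index) -> int:
        if isinstance(label_or_index, str):
            return int(self.counts[PATTERN_LABELS.index(label_or_index)])
        return int(self.counts[label_or_index])

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        return PatternCounts(self.counts + other.counts)

    def to_record(self) -> str:
        """Two-line delimited record headed ``EEE,EEC,...,CCC`` (canonical order)."""
        header = ",".join(PATTERN_LABELS)
        body = ",".join(str(int(v)) for v in self.counts)
        return f"{header}\n{body}\n"

    @classmethod
    def from_record(cls, text: str) -> "PatternCounts":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if len(lines) != 2 or [c.strip() for c in lines[0].split(",")] != list(PATTERN_LABELS):
            raise ValueError("expected a header line 'EEE,...,CCC' and one count line")
        return cls(np.array([int(v) for v in lines[1].split(",")]))


def _probabilities_from_vector(theta: np.ndarray) -> np.ndarray:
    """Pattern probabilities from a (D, F, J1, J2, J3, R) vector."""
    d, f, j1, j2, j3, r = theta
    p = np.empty(8)
    # Gist route: output on test t independently with probability Jt.
    gist = (1.0 - d) * r
    for idx in range(8):
        x1, x2, x3 = (idx >> 2) & 1, (idx >> 1) & 1, idx & 1
        q = (j1 if x1 else 1 - j1) * (j2 if x2 else 1 - j2) * (j3 if x3 else 1 - j3)
        p[idx] = gist * q
    # Verbatim route: recalled while direct access survives, then lost for good.
    p[7] += d * (1 - f) * (1 - f)          # CCC
    p[6] += d * (1 - f) * f                # CCE
    p[4] += d * f                          # CEE
    # Neither trace: never recalled.
    p[0] += (1.0 - d) * (1.0 - r)          # EEE
    return p


def _probabilities_gradient(theta: np.ndarray) -> np.ndarray:
    """Jacobian d(pattern probabilities)/d(theta), shape (8, 6)."""
    d, f, j1, j2, j3, r = theta
    jac = np.zeros((8, 6))
    js = (j1, j2, j3)
    for idx in range(8):
        x = ((idx >> 2) & 1, (idx >> 1) & 1, idx & 1)
        q = [js[t] if x[t] else 1 - js[t] for t in range(3)]
        prod = q[0] * q[1] * q[2]
        jac[idx, 0] += -r * prod                     # d/dD of gist
        jac[idx, 5] += (1 - d) * prod                # d/dR of gist
        for t in range(3):
            other = q[(t + 1) % 3] * q[(t + 2) % 3]
            jac[idx, 2 + t] += (1 - d) * r * other * (1 if x[t] else -1)
    jac[7, 0] += (1 - f) ** 2
    jac[7, 1] += -2 * d * (1 - f)
    jac[6, 0] += (1 - f) * f
    jac[6, 1] += d * (1 - 2 * f)
    jac[4, 0] += f
    jac[4, 1] += d
    jac[0, 0] += -(1 - r)
    jac[0, 5] += -(1 - d)
    return jac


def pattern_probabilities(params: DualRetrievalParams) -> PatternDistribution:
    """Distribution over the 8 three-test recall patterns implied by ``params``.

    The verbatim route contributes only to the monotone patterns CCC, CCE,
    CEE (direct access, once lost, never returns); the gist route
    contributes to every pattern through the per-test familiarity
    judgments; items with neither trace land in EEE.
    """
    return PatternDistribution(_probabilities_from_vector(params.to_array()))


def simulate_patterns(
    params: DualRetrievalParams, n_items: int, seed: int
) -> PatternCounts:
    """Draw ``n_items`` i.i.d. recall patterns and tally them.

    Reproducible given ``seed``; the multinomial draw consumes the
    generator once, with cells in canonical pattern-index order.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    rng = np.random.default_rng(seed)
    probs = pattern_probabilities(params).probabilities
    return PatternCounts(rng.multinomial(n_items, probs))
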