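"""Synthetic JOL-reactivity experiments from a known generative truth.

The generator emulates a 2 (list organization: blocked vs randomized) x 3
(JOL condition: item-level, list-level, none) between-subjects free-recall
experiment: 240 participants, 40 study words (8 exemplars from each of 5
taxonomic categories) presented in five 8-word lists, three consecutive
recall tests.  Recall outcomes are drawn from the dual-retrieval model
with condition-specific true parameters; output order within a test is
produced by a category-biased sequential draw so that category clustering
(ARC) is controllable.  JOL ratings are drawn on the task scales (0-100
per item, 0-8 per list) but do not feed back into recall: reactivity lives
entirely in the condition-specific model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import DualRetrievalParams, pattern_probabilities

__all__ = [
    "ORGANIZATIONS",
    "JOL_CONDITIONS",
    "DEFAULT_TRUE_PARAMS",
    "ExperimentConfig",
    "StudyList",
    "build_lists",
    "simulate_recall",
    "simulate_jols",
    "generate_experiment",
    "max_same_category_run",
]

ORGANIZATIONS: tuple[str, ...] = ("blocked", "randomized")
JOL_CONDITIONS: tuple[str, ...] = ("item", "list", "none")

# Condition-specific generative truth: one dual-retrieval parameter set
# (D, F, J1, J2, J3, R) per cell of the 2x3 design.  The defaults encode
# the reactivity structure of interest: for randomized lists the item-JOL
# cell has elevated familiarity J1 relative to the no-JOL cell, the
# list-JOL cell has reduced direct access D and reconstruction R; for
# blocked lists the list-JOL cell has elevated forgetting F and J2.
DEFAULT_TRUE_PARAMS: dict = {
    ("blocked", "item"): DualRetrievalParams.from_array([0.42, 0.05, 0.40, 0.52, 0.79, 0.19]),
    ("blocked", "list"): DualRetrievalParams.from_array([0.42, 0.10, 0.50, 0.69, 0.78, 0.20]),
    ("blocked", "none"): DualRetrievalParams.from_array([0.40, 0.05, 0.42, 0.62, 0.84, 0.20]),
    ("randomized", "item"): DualRetrievalParams.from_array([0.37, 0.06, 0.54, 0.64, 0.84, 0.20]),
    ("randomized", "list"): DualRetrievalParams.from_array([0.25, 0.09, 0.71, 0.74, 0.91, 0.10]),
    ("randomized", "none"): DualRetrievalParams.from_array([0.33, 0.06, 0.34, 0.58, 0.84, 0.15]),
}

TRIAL_COLUMNS = [
    "participant_id", "organization", "jol_condition", "word", "category",
    "list_index", "serial_position", "item_jol", "list_jol",
    "recalled_t1", "recalled_t2", "recalled_t3",
    "output_position_t1", "output_position_t2", "output_position_t3",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design knobs of the simulated experiment.

    ``clustering_weight`` in [0, 1] sets the probability that, during
    recall output, the next reported word stays within the current
    category when possible; 0 gives a uniform output order (chance ARC),
    1 gives perfectly contiguous categories (ARC = 1).
    """

    n_participants: int = 240
    n_categories: int = 5
    exemplars_per_category: int = 8
    organizations: tuple = ORGANIZATIONS
    jol_conditions: tuple = JOL_CONDITIONS
    max_run_length: int = 3
    true_params: Mapping = field(default_factory=lambda: dict(DEFAULT_TRUE_PARAMS))
    item_jol_mean: float = 50.0
    item_jol_sd: float = 25.0
    list_jol_means: Mapping = field(
        default_factory=lambda: {"blocked": 4.89, "randomized": 3.73}
    )
    list_jol_sds: Mapping = field(
        default_factory=lambda: {"blocked": 1.19, "randomized": 1.06}
    )
    clustering_weight: float = 0.5
    lexicon: Optional[Mapping] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.clustering_weight <= 1.0):
            raise ValueError("clustering_weight must lie in [0, 1]")
        if not (0.0 <= self.item_jol_mean <= 100.0):
            raise ValueError("item_jol_mean must lie on the 0-100 scale")
        for org, mean in self.list_jol_means.items():
            if not (0.0 <= mean <= 8.0):
                raise ValueError(f"list_jol_means[{org!r}] must lie on the 0-8 scale")
        if self.n_categories < 1 or self.exemplars_per_category < 1:
            raise ValueError("need at least one category and one exemplar")

    @property
    def n_items(self) -> int:
        return self.n_categories * self.exemplars_per_category

    def words_by_category(self) -> dict:
        if self.lexicon is not None:
            out = {}
            for cat, words in self.lexicon.items():
                if len(words) < self.exemplars_per_category:
                    raise ValueError(f"lexicon category {cat!r} is too small")
                out[str(cat)] = [str(w) for w in words[: self.exemplars_per_category]]
            if len(out) != self.n_categories:
                raise ValueError("lexicon must provide exactly n_categories categories")
            return out
        return {
            f"cat{c + 1}": [
                f"cat{c + 1}_{i + 1}" for i in range(self.exemplars_per_category)
            ]
            for c in range(self.n_categories)
        }


@dataclass(frozen=True)
class StudyList:
    """One presented list: ordered (word, category) pairs."""

    items: tuple
    organization: str
    list_index: int

    @property
    def categories(self) -> tuple:
        return tuple(cat for _, cat in self.items)


def max_same_category_run(labels: Sequence) -> int:
    """Length of the longest run of identical category labels."""
    best = run = 0
    prev = object()
    for lab in labels:
        run = run + 1 if lab == prev else 1
        best = max(best, run)
        prev = lab
    return best


def build_lists(
    config: ExperimentConfig, organization: str, participant_seed: int
) -> list[StudyList]:
    """Build one participant's study lists for the given organization.

    Blocked: the exemplars of each category are presented consecutively,
    with category order and within-category order shuffled; each category
    block is one list.  Randomized: a global order of all words is
    rejection-sampled until no same-category run exceeds
    ``max_run_length``, then cut into lists of ``exemplars_per_category``
    items.  Deterministic given ``participant_seed``.
    """
    if organization not in ORGANIZATIONS:
        raise ValueError(f"unknown organization {organization!r}")
    rng = np.random.default_rng(participant_seed)
    words = config.words_by_category()
    categories = list(words)

    if organization == "blocked":
        order = rng.permutation(len(categories))
        lists = []
        for li, ci in enumerate(order):
            cat = categories[ci]
            ws = list(words[cat])
            rng.shuffle(ws)
            lists.append(
                StudyList(tuple((w, cat) for w in ws), "blocked", li)
            )
        return lists

    if config.n_categories == 1 and config.max_run_length < config.exemplars_per_category:
        raise ValueError(
            "randomized order with a single category cannot satisfy the "
            f"run-length constraint {config.max_run_length}"
        )
    pool = [(w, cat) for cat in categories for w in words[cat]]
    for _ in range(10_000):
        perm = rng.permutation(len(pool))
        ordered = [pool[i] for i in perm]
        if max_same_category_run([c for _, c in ordered]) <= config.max_run_length:
            k = config.exemplars_per_category
            return [
                StudyList(tuple(ordered[i : i + k]), "randomized", i // k)
                for i in range(0, len(ordered), k)
            ]
    raise ValueError(
        "could not satisfy the same-category run-length constraint in "
        "10,000 rejection-sampling attempts"
    )


def _output_order(
    recalled: np.ndarray, categories: Sequence, weight: float, rng
) -> np.ndarray:
    """Category-biased output order over the recalled items.

    Returns 1-based output positions (0 for unrecalled items).  With
    probability ``weight`` the next output stays within the current
    category while any of its recalled items remain; otherwise (and for
    the first output) the next item is uniform over all remaining ones.
    """
    positions = np.zeros(len(categories), dtype=int)
    remaining = [i for i in np.flatnonzero(recalled)]
    rank = 0
    current_cat = None
    while remaining:
        same = [i for i in remaining if categories[i] == current_cat]
        if same and rng.random() < weight:
            choice = same[rng.integers(len(same))]
        else:
            choice = remaining[rng.integers(len(remaining))]
        rank += 1
        positions[choice] = rank
        current_cat = categories[choice]
        remaining.remove(choice)
    return positions


def simulate_recall(
    lists: Sequence[StudyList],
    params: DualRetrievalParams,
    clustering_weight: float,
    seed: int,
) -> pd.DataFrame:
    """Three-test recall outcomes and output orders for one participant.

    Each item's (t1, t2, t3) pattern is drawn i.i.d. from the
    dual-retrieval pattern distribution; items are independent given the
    condition's parameters.  Output positions are assigned per test by the
    category-biased sequential draw described in
    :class:`ExperimentConfig`.
    """
    items = [(w, c) for sl in lists for (w, c) in sl.items]
    list_idx = [sl.list_index for sl in lists for _ in sl.items]
    n = len(items)
    rng = np.random.default_rng(seed)
    probs = pattern_probabilities(params).probabilities
    idx = rng.choice(8, size=n, p=probs)
    recalled = np.stack(
        [(idx >> 2) & 1, (idx >> 1) & 1, idx & 1], axis=1
    ).astype(bool)
    cats = [c for _, c in items]
    out = {
        "word": [w for w, _ in items],
        "category": cats,
        "list_index": list_idx,
        "serial_position": np.arange(1, n + 1),
    }
    for t in range(3):
        pos = _output_order(recalled[:, t], cats, clustering_weight, rng)
        out[f"recalled_t{t + 1}"] = recalled[:, t].astype(int)
        out[f"output_position_t{t + 1}"] = pd.array(
            [p if p > 0 else None for p in pos], dtype="Int64"
        )
    return pd.DataFrame(out)


def simulate_jols(
    config: ExperimentConfig, condition: str, organization: str, seed: int
) -> np.ndarray:
    """JOL ratings for one participant.

    Item condition: one integer rating in [0, 100] per study word, from a
    normal draw rounded and clipped to the scale.  List condition: one
    integer in [0, 8] per 8-word list, with an organization-specific mean.
    """
    if condition not in ("item", "list"):
        raise ValueError("JOLs are only collected in the item and list conditions")
    rng = np.random.default_rng(seed)
    if condition == "item":
        draws = rng.normal(config.item_jol_mean, config.item_jol_sd, config.n_items)
        return np.clip(np.rint(draws), 0, 100).astype(int)
    mean = config.list_jol_means[organization]
    sd = config.list_jol_sds[organization]
    draws = rng.normal(mean, sd, config.n_categories)
    return np.clip(np.rint(draws), 0, 8).astype(int)


def _cell_allocation(config: ExperimentConfig) -> list:
    """Assign participants to the 6 cells as evenly as possible (within 1)."""
    cells = [
        (org, jol)
        for org in config.organizations
        for jol in config.jol_conditions
    ]
    base, extra = divmod(config.n_participants, len(cells))
    alloc = []
    for i, cell in enumerate(cells):
        alloc.extend([cell] * (base + (1 if i < extra else 0)))
    return alloc


def generate_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Generate the full trial-level table of one synthetic experiment.

    One row per participant x study word, with the condition labels, JOL
    values on their task scales, and three-test recall flags plus output
    positions.  Fully reproducible from ``config.seed``.
    """
    alloc = _cell_allocation(config)
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(len(alloc))
    frames = []
    for pidx, ((org, jol), seq) in enumerate(zip(alloc, seeds)):
        s_lists, s_recall, s_jol = (
            int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(3)
        )
        lists = build_lists(config, org, s_lists)
        params = config.true_params[(org, jol)]
        df = simulate_recall(lists, params, config.clustering_weight, s_recall)
        df.insert(0, "participant_id", f"p{pidx + 1:04d}")
        df.insert(1, "organization", org)
        df.insert(2, "jol_condition", jol)
        item_jol = pd.array([None] * len(df), dtype="Int64")
        list_jol = pd.array([None] * len(df), dtype="Int64")
        if jol == "item":
            item_jol = pd.array(
                simulate_jols(config, "item", org, s_jol), dtype="Int64"
            )
        elif jol == "list":
            values = simulate_jols(config, "list", org, s_jol)
            list_jol = pd.array([None] * len(df), dtype="Int64")
            for li, v in zip(sorted(set(df["list_index"])), values):
                # attach to the list-boundary row (last word of the list)
                boundary = df.index[df["list_index"] == li].max()
                list_jol[boundary] = int(v)
        df["item_jol"] = item_jol
        df["list_jol"] = list_jol
        frames.append(df[TRIAL_COLUMNS])
    return pd.concat(frames, ignore_index=True)
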