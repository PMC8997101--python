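"""Weighted Cohen's kappa on ordinal ratings, category merging, and the
observer reliability gate.

Kappa is computed with *disagreement* weights over a declared ordered scale:

    kappa = 1 - (sum_ij w_ij O_ij) / (sum_ij w_ij E_ij)

where O is the observed joint proportion table of the two raters, E the
chance-expected table (outer product of the marginals) and w_ij the linear
(|i-j| / (K-1)) or quadratic (((i-j)/(K-1))^2) disagreement weight.  A value
of 1 is perfect agreement; 0 is chance-level; negative values are worse than
chance.

The gate follows the common benchmark that kappa >= 0.61 ("substantial" on
the Landis–Koch scale) qualifies an observer's data for inclusion.

Which weight scheme (linear vs quadratic) a given software package used for a
published kappa is often unstated; the default here is **linear**, with
quadratic available.  Reported values from other software may therefore
differ even on identical ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

DEFAULT_GATE_THRESHOLD = 0.61

#: Landis & Koch interpretation bands (upper bound exclusive except the last).
LANDIS_KOCH_BANDS = (
    (0.0, "poor"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def landis_koch_label(kappa: float) -> str:
    """Interpretation label for a kappa value (reporting only)."""
    if kappa <= 0:
        return "poor"
    label = "slight"
    for lower, name in LANDIS_KOCH_BANDS[1:]:
        if kappa >= lower:
            label = name
    return label


@dataclass(frozen=True)
class KappaResult:
    """A weighted kappa with its building blocks.

    ``observed_agreement`` / ``expected_agreement`` are the weighted
    agreements 1 - sum(w*O) and 1 - sum(w*E).  ``degenerate`` marks the case
    of both raters constant and identical (kappa defined as 1);
    ``undefined`` marks zero expected disagreement with non-zero observed
    disagreement (kappa is NaN).
    """

    kappa: float
    observed_agreement: float
    expected_agreement: float
    weights: str
    n_items: int
    degenerate: bool = False
    undefined: bool = False

    @property
    def label(self) -> str:
        return landis_koch_label(self.kappa)


def disagreement_weights(n_categories: int, scheme: str = "linear") -> np.ndarray:
    """K x K disagreement weight matrix over an ordered scale."""
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.zeros((1, 1))
    idx = np.arange(n_categories)
    diff = np.abs(idx[:, None] - idx[None, :]) / (n_categories - 1)
    if scheme == "linear":
        return diff
    if scheme == "quadratic":
        return diff ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def kappa_from_counts(table: np.ndarray, weights: str = "linear") -> KappaResult:
    """Weighted kappa from a K x K contingency table of rating counts
    (rows = rater 1, columns = rater 2, category order = scale order)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    n = table.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    k = table.shape[0]
    w = disagreement_weights(k, weights)
    observed = table / n
    marg1 = observed.sum(axis=1)
    marg2 = observed.sum(axis=0)
    expected = np.outer(marg1, marg2)
    d_obs = float((w * observed).sum())
    d_exp = float((w * expected).sum())
    if d_exp == 0.0:
        if d_obs == 0.0:
            # both raters constant and equal: perfect but degenerate
            return KappaResult(1.0, 1.0, 1.0, weights, int(n), degenerate=True)
        return KappaResult(float("nan"), 1.0 - d_obs, 1.0, weights, int(n), undefined=True)
    return KappaResult(1.0 - d_obs / d_exp, 1.0 - d_obs, 1.0 - d_exp, weights, int(n))


def _as_index(ratings: Sequence, categories: Sequence) -> np.ndarray:
    cat_index = {c: i for i, c in enumerate(categories)}
    try:
        return np.array([cat_index[r] for r in ratings], dtype=int)
    except KeyError as err:
        raise ValueError(f"rating {err.args[0]!r} outside the declared scale {list(categories)}") from None


def weighted_kappa(ratings1: Sequence, ratings2: Sequence,
                   categories: Optional[Sequence] = None,
                   weights: str = "linear") -> KappaResult:
    """Weighted Cohen's kappa of two equal-length rating vectors.

    ``categories`` declares the ordered scale; by default it is the sorted
    union of the observed ratings.  Declaring the full scale matters: unused
    extreme categories change the weight normalisation.
    """
    r1 = list(ratings1)
    r2 = list(ratings2)
    if len(r1) != len(r2):
        raise ValueError(f"rating vectors differ in length ({len(r1)} vs {len(r2)})")
    if len(r1) == 0:
        raise ValueError("need at least one rated item")
    if categories is None:
        categories = sorted(set(r1) | set(r2))
    i1 = _as_index(r1, categories)
    i2 = _as_index(r2, categories)
    k = len(categories)
    table = np.zeros((k, k))
    np.add.at(table, (i1, i2), 1.0)
    return kappa_from_counts(table, weights)


def parse_partition(spec: str, categories: Sequence) -> list[tuple]:
    """Parse a merge spec like ``"12|3|45"`` into category blocks.

    Each character (or comma-separated token) names a category; blocks are
    separated by ``|``.
    """
    blocks = []
    for part in spec.split("|"):
        tokens = part.split(",") if "," in part else list(part)
        block = []
        for tok in tokens:
            matches = [c for c in categories if str(c) == tok]
            if not matches:
                raise ValueError(f"partition token {tok!r} is not a category of {list(categories)}")
            block.append(matches[0])
        blocks.append(tuple(block))
    return blocks


def merge_and_rate(ratings1: Sequence, ratings2: Sequence,
                   partition: Union[str, Iterable[Iterable]],
                   categories: Optional[Sequence] = None,
                   weights: str = "linear") -> KappaResult:
    """Recode both raters onto merged category blocks, then compute kappa.

    ``partition`` must cover the declared scale exactly once (e.g. the
    (12)(3)(45) merge of a 5-point locomotion scale).  Blocks are ordered by
    their lowest member, preserving the ordinal structure.
    """
    r1 = list(ratings1)
    r2 = list(ratings2)
    if categories is None:
        categories = sorted(set(r1) | set(r2))
    if isinstance(partition, str):
        blocks = parse_partition(partition, categories)
    else:
        blocks = [tuple(b) for b in partition]
    flat = [c for b in blocks for c in b]
    if len(flat) != len(set(flat)):
        raise ValueError("partition blocks overlap")
    if set(flat) != set(categories):
        missing = set(categories) - set(flat)
        raise ValueError(f"partition does not cover the scale; missing {sorted(missing, key=str)}")
    blocks = sorted(blocks, key=lambda b: min(categories.index(c) if hasattr(categories, "index")
                                              else list(categories).index(c) for c in b))
    recode = {c: i for i, b in enumerate(blocks) for c in b}
    m1 = [recode[r] for r in r1]
    m2 = [recode[r] for r in r2]
    return weighted_kappa(m1, m2, categories=list(range(len(blocks))), weights=weights)


def observer_kappas(ratings: pd.DataFrame,
                    merge: Optional[str] = None,
                    categories: Optional[Sequence] = None,
                    weights: str = "linear") -> pd.DataFrame:
    """Per-observer kappa against the reference rating.

    ``ratings`` follows the rater-response schema (``observer_id``,
    ``item_id``, ``rating``, ``reference``).  Returns one row per observer
    with kappa, agreement components and the Landis–Koch label.
    """
    required = {"observer_id", "rating", "reference"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table lacks columns {sorted(missing)}")
    rows = []
    for obs, sub in ratings.groupby("observer_id", sort=True):
        if merge is None:
            res = weighted_kappa(sub["rating"], sub["reference"],
                                 categories=categories, weights=weights)
        else:
            res = merge_and_rate(sub["rating"], sub["reference"], merge,
                                 categories=categories, weights=weights)
        rows.append({
            "observer_id": obs,
            "kappa": res.kappa,
            "observed_agreement": res.observed_agreement,
            "expected_agreement": res.expected_agreement,
            "n_items": res.n_items,
            "weights": res.weights,
            "degenerate": res.degenerate,
            "undefined": res.undefined,
            "label": res.label,
        })
    return pd.DataFrame(rows)


def gate_observers(results: Mapping[str, Union[KappaResult, float]],
                   threshold: float = DEFAULT_GATE_THRESHOLD) -> tuple[set, set]:
    """Split observers into (passed, failed) at the inclusive kappa gate.

    An observer passes iff kappa >= threshold; undefined kappas fail.  The
    passed set is what feeds the trained-observer registry of the validation
    stage.
    """
    passed: set = set()
    failed: set = set()
    for obs, res in results.items():
        kappa = res.kappa if isinstance(res, KappaResult) else float(res)
        if not np.isnan(kappa) and kappa >= threshold:
            passed.add(obs)
        else:
            failed.add(obs)
    return passed, failed
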