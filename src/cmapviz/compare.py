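"""Superpose predicted and model-derived contact maps and score satisfaction.

The superposition partitions the union of the two maps' contacts into three
classes — matched (in both), model-only and predicted-only — the black, red
and grey points of the comparison display.  The fraction of selected predicted
contacts realized in the model (the precision of the prediction with respect
to the model) serves as a proxy for model quality: a model that satisfies the
confident long-range predictions is more likely to be correct.

Defaults follow the usual contact-evaluation conventions: long-range means
sequence separation >= 23, and the evaluation set is the top-L/2 predictions
for a sequence of length L.
"""

from __future__ import annotations

import warnings

from .errors import ValidationError
from .model import (
    LONG_RANGE_MIN_SEP,
    ContactMap,
    MatchClassification,
    filter_by_separation,
    select_top,
)


def _check_compatible(predicted: ContactMap, model: ContactMap) -> None:
    if predicted.seq_length != model.seq_length:
        raise ValidationError(
            f"sequence length mismatch: predicted {predicted.seq_length} vs "
            f"model {model.seq_length}"
        )
    if (
        predicted.sequence is not None
        and model.sequence is not None
        and predicted.sequence != model.sequence
    ):
        raise ValidationError(
            "sequences of predicted and model maps disagree; refusing to compare"
        )


def superpose(
    predicted: ContactMap,
    model: ContactMap,
    min_sep: int = 0,
    top_n: int | None = None,
) -> MatchClassification:
    """Classify contacts of two superposed maps of the same sequence.

    Both maps are filtered to separation >= ``min_sep``; when ``top_n`` is
    given the predicted map is first reduced to its ``top_n`` highest-scoring
    contacts.  Returns the matched / model-only / predicted-only partition.
    """
    _check_compatible(predicted, model)
    if top_n is not None:
        predicted = select_top(predicted, top_n)
    p = filter_by_separation(predicted, min_sep).pairs()
    m = filter_by_separation(model, min_sep).pairs()
    return MatchClassification(
        matched=frozenset(p & m),
        model_only=frozenset(m - p),
        predicted_only=frozenset(p - m),
    )


def satisfaction_score(
    predicted: ContactMap,
    model: ContactMap,
    min_sep: int = LONG_RANGE_MIN_SEP,
    top_n: int | None = None,
) -> float:
    """Fraction of selected predicted contacts realized in the model.

    The predicted map is reduced to its ``top_n`` highest-scoring contacts
    (default L/2, rounded down), both maps are filtered to separation
    >= ``min_sep``, and the score is |matched| divided by the number of
    selected predictions surviving the separation filter.  Returns 0.0 (with a
    warning) when no predictions survive.
    """
    _check_compatible(predicted, model)
    if top_n is None:
        top_n = predicted.seq_length // 2
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    selected = filter_by_separation(select_top(predicted, top_n), min_sep)
    if len(selected) == 0:
        warnings.warn(
            "no predicted contacts survive selection; satisfaction undefined, "
            "returning 0.0"
        )
        return 0.0
    realized = selected.pairs() & filter_by_separation(model, min_sep).pairs()
    return len(realized) / len(selected)


def classification_table(classification: MatchClassification) -> str:
    """Export a classification as 3-column text ``i j class``, sorted by (i, j)."""
    rows = [(i, j, "matched") for i, j in classification.matched]
    rows += [(i, j, "model-only") for i, j in classification.model_only]
    rows += [(i, j, "predicted-only") for i, j in classification.predicted_only]
    return "\n".join(f"{i}\t{j}\t{cls}" for i, j, cls in sorted(rows)) + "\n"
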