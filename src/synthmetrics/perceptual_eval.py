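"""Visual Turing test construction/scoring and cosine k-NN memorization audit.

A visual Turing test presents a blinded observer with a shuffled mix of
real and synthetic images (default 50 of each) to classify as real or
synthetic.  Responses are scored as a confusion matrix with the *real*
class positive:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)      (real images detected as real)
    specificity = TN / (TN + FP)      (synthetic images detected as synthetic)

Accuracy near 0.5 on a balanced session means the observer cannot tell the
two sources apart.

The cosine k-NN audit ranks, for every real image embedding, the k most
similar synthetic embeddings; the reals with the highest top-1 similarity
are laid out beside their nearest synthetic counterparts so a reviewer can
judge visually whether near neighbors are copies or genuinely novel.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .embedding import FeatureMatrix


@dataclass
class TuringSession:
    """A blinded presentation list plus its separately-held answer key.

    ``items`` is the shuffled presentation order: (item_id, image_ref)
    pairs with no label information.  ``key`` maps item_id -> true label.
    """

    items: list[tuple[str, str]]
    key: dict[str, str]
    n_real: int
    n_synth: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_real != self.n_synth:
            raise ValueError("sessions are balanced: n_real must equal n_synth")
        if len(self.items) != self.n_real + self.n_synth:
            raise ValueError("item count does not match n_real + n_synth")


@dataclass
class ConfusionCounts:
    """Turing-test confusion matrix; the real class is positive.

    TP = real called real, FN = real called synthetic,
    TN = synthetic called synthetic, FP = synthetic called real.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class NeighborTable:
    """Per-real ranked synthetic neighbors under cosine similarity.

    ``indices[i]`` holds the k synthetic row indices most similar to real
    row i, in non-increasing similarity order (ties broken by index);
    ``similarities`` holds the matching cosine values.
    """

    indices: np.ndarray
    similarities: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.similarities = np.asarray(self.similarities, dtype=np.float64)
        if np.any(np.diff(self.similarities, axis=1) > 1e-12):
            raise ValueError("similarities must be non-increasing within each row")
        if np.any(np.abs(self.similarities) > 1.0 + 1e-9):
            raise ValueError("cosine similarities must lie in [-1, 1]")


def build_session(
    real_refs: list[str],
    synth_refs: list[str],
    n_each: int = 50,
    seed: int = 0,
) -> TuringSession:
    """Draw a balanced, seeded, shuffled Turing-test session.

    Samples ``n_each`` references per class without replacement and shuffles
    the combined list; the answer key is stored apart from the presentation
    list so observers stay blinded.
    """
    if n_each > len(real_refs) or n_each > len(synth_refs):
        raise ValueError(
            f"need at least {n_each} refs per class, have "
            f"{len(real_refs)} real / {len(synth_refs)} synthetic"
        )
    rng = np.random.default_rng(seed)
    chosen_real = [real_refs[i] for i in rng.choice(len(real_refs), n_each, replace=False)]
    chosen_synth = [
        synth_refs[i] for i in rng.choice(len(synth_refs), n_each, replace=False)
    ]
    labeled = [(ref, "real") for ref in chosen_real] + [
        (ref, "synthetic") for ref in chosen_synth
    ]
    order = rng.permutation(len(labeled))
    items = []
    key = {}
    for pos, j in enumerate(order):
        ref, label = labeled[j]
        item_id = f"item_{pos:03d}"
        items.append((item_id, ref))
        key[item_id] = label
    return TuringSession(items=items, key=key, n_real=n_each, n_synth=n_each, seed=seed)


def score_responses(session: TuringSession, responses: dict[str, str]) -> ConfusionCounts:
    """Score one observer's per-item labels against the session key.

    ``responses`` maps item_id -> "real" or "synthetic"; exactly one
    response per presented item is required.
    """
    expected = {item_id for item_id, _ in session.items}
    missing = sorted(expected - set(responses))
    extra = sorted(set(responses) - expected)
    if missing or extra:
        raise ValueError(f"response mismatch; missing={missing}, unexpected={extra}")
    tp = fp = tn = fn = 0
    for item_id, _ in session.items:
        truth, call = session.key[item_id], responses[item_id]
        if call not in ("real", "synthetic"):
            raise ValueError(f"invalid label {call!r} for {item_id}")
        if truth == "real":
            tp += call == "real"
            fn += call == "synthetic"
        else:
            tn += call == "synthetic"
            fp += call == "real"
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _round_half_up(x: float, digits: int = 2) -> float:
    factor = 10**digits
    return math.floor(x * factor + 0.5) / factor


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity from a confusion matrix.

    Returns full-precision values plus half-up 2-decimal roundings
    (``*_2dp``) for display.  A zero denominator yields ``None`` for the
    affected metric rather than raising.
    """
    out: dict[str, float | None] = {}
    pairs = {
        "accuracy": (c.tp + c.tn, c.total),
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = None
            out[f"{name}_2dp"] = None
        else:
            value = num / den
            out[name] = value
            out[f"{name}_2dp"] = _round_half_up(value)
    return out


def cosine_neighbors(
    real_f: FeatureMatrix, synth_f: FeatureMatrix, k: int = 4
) -> NeighborTable:
    """Rank the k most cosine-similar synthetic embeddings per real embedding.

    Deterministic: exact similarities, ties broken by smaller synthetic
    index.  Zero-norm vectors are rejected (cosine undefined).
    """
    if real_f.d != synth_f.d:
        raise ValueError(f"dimension mismatch: {real_f.d} vs {synth_f.d}")
    if k < 1 or k > synth_f.n:
        raise ValueError(f"k={k} must be in [1, {synth_f.n}]")
    for name, mat in (("real", real_f.values), ("synthetic", synth_f.values)):
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0):
            idx = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"zero-norm {name} vector at row {idx}")
    a = real_f.values / np.linalg.norm(real_f.values, axis=1, keepdims=True)
    b = synth_f.values / np.linalg.norm(synth_f.values, axis=1, keepdims=True)
    sims = np.clip(a @ b.T, -1.0, 1.0)
    # lexsort: primary key descending similarity, secondary ascending index
    col = np.arange(synth_f.n)
    indices = np.empty((real_f.n, k), dtype=np.int64)
    for i in range(real_f.n):
        order = np.lexsort((col, -sims[i]))
        indices[i] = order[:k]
    ranked = np.take_along_axis(sims, indices, axis=1)
    return NeighborTable(indices=indices, similarities=ranked, k=k)


def top_matches(table: NeighborTable, n_real_shown: int = 2) -> dict:
    """Montage layout: the reals with the highest top-1 similarity, each
    beside its k ranked synthetic neighbors.

    Returns a JSON-friendly spec with one row per selected real:
    ``{"rows": [{"real": i, "neighbors": [...], "similarities": [...]}],
    "n_cols": 1 + k}``.  Top-1 ties resolve to the lower real index.
    """
    n_real = table.indices.shape[0]
    if n_real_shown > n_real:
        raise ValueError(f"cannot show {n_real_shown} of {n_real} reals")
    top1 = table.similarities[:, 0]
    order = np.lexsort((np.arange(n_real), -top1))[:n_real_shown]
    rows = [
        {
            "real": int(i),
            "neighbors": [int(j) for j in table.indices[i]],
            "similarities": [float(s) for s in table.similarities[i]],
        }
        for i in order
    ]
    return {"rows": rows, "n_cols": 1 + table.k}


def session_to_csv(session: TuringSession, presentation_path, key_path) -> None:
    """Persist a session as two CSVs: the blinded list and the answer key."""
    with open(presentation_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item_id", "image_ref"])
        writer.writerows(session.items)
    with open(key_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item_id", "label"])
        for item_id, _ in session.items:
            writer.writerow([item_id, session.key[item_id]])


def responses_from_csv(path) -> dict[str, str]:
    """Read observer responses from a CSV with columns item_id,label."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["item_id"]] = row["label"]
    return out
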