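"""Two-stage selection of cessation-related short texts.

Stage one is a keyword query: keep texts containing a quit/stop token and a
smoking-family token while rejecting texts containing any of a small set of
off-topic exclusion tokens (fire, marijuana, mj, pot, pott, weed).  Stage two
is a trained relevance classifier that mimics a human coder's judgement of
whether the author is really discussing smoking cessation, applied on top of
the keyword filter to produce the analyzed daily count series.

Matching is whole-token and case-insensitive: exclusion terms are short, so
substring matching would reject texts like "harry potter wants to quit
smoking" that a human coder would keep.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .streams_io import DailySeries

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

# Prefix stems realizing "variations on quit" (the source lists only
# "quitting" explicitly; the closed stem sets are a package decision).
QUIT_TOKENS = frozenset({"quit", "quits", "quitting", "quitted",
                         "stop", "stops", "stopping", "stopped"})
SMOKE_TOKENS = frozenset({"smoking", "smoke", "smokes"})
EXCLUSION_TOKENS = frozenset({"fire", "marijuana", "mj", "pot", "pott", "weed"})

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class ShortText:
    text: str
    timestamp: date
    label: Optional[str] = None


@dataclass(frozen=True)
class ClassifierReport:
    precision: float
    recall: float
    n_train: int
    n_eval: int
    threshold: float


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def keyword_match(text: str) -> bool:
    """True iff the text passes the cessation keyword query.

    Requires a quit/stop token AND a smoking-family token, and no exclusion
    token.  Empty text never matches.
    """
    tokens = set(tokenize(text))
    if not tokens:
        return False
    if tokens & EXCLUSION_TOKENS:
        return False
    return bool(tokens & QUIT_TOKENS) and bool(tokens & SMOKE_TOKENS)


class RelevanceClassifier:
    """Linear relevance scorer over token counts with a decision threshold."""

    version = "awarelift-relevance-1"

    def __init__(self, vectorizer, model, threshold: float):
        self._vectorizer = vectorizer
        self._model = model
        self.threshold = float(threshold)

    def score(self, texts: Sequence[str]) -> np.ndarray:
        """Relevance probability for each text."""
        X = self._vectorizer.transform(texts)
        return self._model.predict_proba(X)[:, 1]

    def predict(self, texts: Sequence[str]) -> np.ndarray:
        return self.score(texts) >= self.threshold

    def save(self, path: str | Path) -> None:
        import pickle
        with open(path, "wb") as fh:
            pickle.dump({"version": self.version, "vectorizer": self._vectorizer,
                         "model": self._model, "threshold": self.threshold}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "RelevanceClassifier":
        import pickle
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        if blob.get("version") != cls.version:
            raise ValueError(f"unsupported classifier artifact {blob.get('version')!r}")
        return cls(blob["vectorizer"], blob["model"], blob["threshold"])


def _precision_recall(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def train_relevance_classifier(
    corpus: Sequence[ShortText],
    split_seed: int = 0,
    *,
    threshold: Optional[float] = None,
) -> tuple[RelevanceClassifier, ClassifierReport]:
    """Train the relevance classifier and report held-out precision/recall.

    The corpus must carry both labels.  The data are split 60/20/20 into
    train / threshold-validation / evaluation, seeded by ``split_seed`` so
    the report is reproducible.  When ``threshold`` is None it is chosen on
    the validation split to maximize F1; pass an explicit value (e.g. 0.5)
    to fix the operating point.
    """
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labeled = [t for t in corpus if t.label is not None]
    texts = [t.text for t in labeled]
    y = np.array([t.label == RELEVANT for t in labeled])
    if y.all() or not y.any():
        raise ValueError("corpus must contain both relevant and irrelevant labels")

    idx = np.arange(len(texts))
    train_idx, rest_idx = train_test_split(idx, test_size=0.4, random_state=split_seed,
                                           stratify=y)
    val_idx, eval_idx = train_test_split(rest_idx, test_size=0.5,
                                         random_state=split_seed + 1,
                                         stratify=y[rest_idx])

    vectorizer = CountVectorizer(token_pattern=r"[a-z0-9]+", lowercase=True)
    X_train = vectorizer.fit_transform([texts[i] for i in train_idx])
    model = LogisticRegression(max_iter=1000, random_state=split_seed)
    model.fit(X_train, y[train_idx])

    clf = RelevanceClassifier(vectorizer, model, 0.5)
    if threshold is None:
        val_scores = clf.score([texts[i] for i in val_idx])
        candidates = np.unique(np.concatenate([[0.5], val_scores]))
        best_f1, best_thr = -1.0, 0.5
        for thr in candidates:
            p, r = _precision_recall(y[val_idx], val_scores >= thr)
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            if f1 > best_f1 + 1e-12:
                best_f1, best_thr = f1, float(thr)
        clf.threshold = best_thr
    else:
        clf.threshold = float(threshold)

    eval_pred = clf.predict([texts[i] for i in eval_idx])
    precision, recall = _precision_recall(y[eval_idx], eval_pred)
    report = ClassifierReport(precision=precision, recall=recall,
                              n_train=len(train_idx), n_eval=len(eval_idx),
                              threshold=clf.threshold)
    return clf, report


def daily_relevant_counts(corpus: Sequence[ShortText],
                          classifier: RelevanceClassifier,
                          label: str = "tweets") -> DailySeries:
    """Per-day count of texts passing the keyword filter AND classified relevant.

    Days inside the corpus span with no relevant text appear with count 0.
    """
    import warnings

    if not corpus:
        warnings.warn("empty corpus: returning empty series", stacklevel=2)
        return DailySeries(pd.DatetimeIndex([]), np.array([]), "raw_count", label)

    kept = [t for t in corpus if keyword_match(t.text)]
    span = pd.date_range(min(t.timestamp for t in corpus),
                         max(t.timestamp for t in corpus), freq="D")
    counts = pd.Series(0, index=span, dtype=float)
    if kept:
        relevant = classifier.predict([t.text for t in kept])
        days = pd.DatetimeIndex([pd.Timestamp(t.timestamp) for t in kept])
        tally = pd.Series(relevant.astype(float)).groupby(days).sum()
        counts.loc[tally.index] += tally
    return DailySeries(span, counts.to_numpy(), "raw_count", label)


def corpus_to_csv(corpus: Sequence[ShortText], path: str | Path) -> None:
    pd.DataFrame({
        "timestamp": [t.timestamp.isoformat() for t in corpus],
        "text": [t.text for t in corpus],
        "label": [t.label or "" for t in corpus],
    }).to_csv(path, index=False)


def corpus_from_csv(path: str | Path) -> list[ShortText]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = {"timestamp", "text"} - set(df.columns)
    if missing:
        raise ValueError(f"corpus file missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples():
        label = getattr(row, "label", "") or None
        out.append(ShortText(text=str(row.text),
                             timestamp=date.fromisoformat(str(row.timestamp)),
                             label=label))
    return out
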