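"""STR-haplogroup association and haplogroup prediction from Y-STR alleles.

The association table reports, per haplogroup (collapsed to a chosen level)
and single-copy locus, the gene diversity and allele spectrum — the
descriptive evidence that STR alleles track haplogroup membership.  The
predictor itself is a categorical (per-locus conditional-independence) Bayes
classifier over smoothed allele frequencies, exposed as an sklearn-style
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .dataset import PopulationDataset, YHaplotype
from .diversity import diversity, spectrum_from_values
from .haplogroups import collapse_to_level, parse_haplogroup_name


def _labels_at_level(ds: PopulationDataset, level: int) -> list[str]:
    return [
        collapse_to_level(parse_haplogroup_name(s.haplogroup), level).bare()
        for s in ds.samples
    ]


def association_table(ds: PopulationDataset, level: int = 0) -> pd.DataFrame:
    """Per (haplogroup, locus): gene diversity and allele spectrum.

    Haplogroups with n < 2 get NaN GD (marked undefined).  Returns a frame
    with columns haplogroup, locus, n, gd, spectrum (allele -> frequency).
    """
    labels = _labels_at_level(ds, level)
    rows = []
    for hg in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == hg]
        for loc in ds.panel.single_copy:
            vals = [ds.samples[i].haplotype.single_value(loc) for i in idx]
            vals = [v for v in vals if v is not None]
            if not vals:
                continue
            spec = spectrum_from_values(vals, "gene")
            gd = diversity(spec).value if len(vals) >= 2 else np.nan
            rows.append(
                {
                    "haplogroup": hg,
                    "locus": loc,
                    "n": len(vals),
                    "gd": gd,
                    "spectrum": spec.frequencies(),
                }
            )
    return pd.DataFrame(rows)


class HaplogroupClassifier(BaseEstimator, ClassifierMixin):
    """Categorical Bayes classifier from single-copy Y-STR alleles.

    Per haplogroup class and locus, allele frequencies are estimated with
    additive smoothing (``pseudocount`` per allele category, shared across
    classes); class priors are training proportions.  Prediction multiplies
    smoothed per-locus frequencies in log space over the loci the query
    covers; multi-copy and missing loci are skipped.
    """

    def __init__(self, level: int = 1, pseudocount: float = 0.5):
        self.level = level
        self.pseudocount = pseudocount

    def fit(self, ds: PopulationDataset, y: Sequence[str] | None = None) -> "HaplogroupClassifier":
        labels = list(y) if y is not None else _labels_at_level(ds, self.level)
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError("need at least two haplogroup classes to train")
        self.classes_ = np.array(classes)
        self.loci_ = tuple(ds.panel.single_copy)
        counts = {c: labels.count(c) for c in classes}
        self.class_prior_ = {c: counts[c] / len(labels) for c in classes}
        # allele category universe per locus, shared across classes
        self.alleles_: dict[str, list[float]] = {}
        tab: dict[str, dict[str, dict[float, int]]] = {c: {} for c in classes}
        for loc in self.loci_:
            seen: set[float] = set()
            for s, lab in zip(ds.samples, labels):
                v = s.haplotype.single_value(loc)
                if v is None:
                    continue
                seen.add(v)
                tab[lab].setdefault(loc, {})
                tab[lab][loc][v] = tab[lab][loc].get(v, 0) + 1
            self.alleles_[loc] = sorted(seen)
        self.freq_: dict[str, dict[str, dict[float, float]]] = {}
        for c in classes:
            self.freq_[c] = {}
            for loc in self.loci_:
                cats = self.alleles_[loc]
                if not cats:
                    continue
                cc = tab[c].get(loc, {})
                total = sum(cc.values()) + self.pseudocount * len(cats)
                if total <= 0:
                    continue
                self.freq_[c][loc] = {
                    a: (cc.get(a, 0) + self.pseudocount) / total for a in cats
                }
        return self

    def _log_posteriors(self, h: YHaplotype) -> tuple[np.ndarray, int]:
        logp = np.array([np.log(self.class_prior_[c]) for c in self.classes_])
        covered = 0
        for loc in self.loci_:
            v = h.single_value(loc) if loc in h.alleles else None
            if v is None:
                continue
            covered += 1
            for k, c in enumerate(self.classes_):
                freqs = self.freq_[c].get(loc)
                if freqs is None:
                    continue
                f = freqs.get(v)
                if f is None:
                    # unseen allele: pure pseudocount mass within the class table
                    cats = len(self.alleles_[loc]) + 1
                    f = self.pseudocount / (self.pseudocount * cats) if self.pseudocount > 0 else 0.0
                logp[k] += np.log(f) if f > 0 else -np.inf
        return logp, covered

    def predict_proba_haplotype(self, h: YHaplotype) -> dict[str, float]:
        logp, covered = self._log_posteriors(h)
        if covered == 0:
            raise ValueError("haplotype covers no profiled locus")
        logp = logp - logp.max()
        p = np.exp(logp)
        p = p / p.sum()
        return {c: float(pi) for c, pi in zip(self.classes_, p)}

    def predict(self, ds: PopulationDataset) -> np.ndarray:
        return np.array(
            [max(p := self.predict_proba_haplotype(s.haplotype), key=lambda c: (p[c], c))
             for s in ds.samples]
        )


@dataclass(frozen=True)
class Prediction:
    posteriors: dict[str, float]
    winner: str
    margin: float


def train_predictor(ds: PopulationDataset, level: int = 1, pseudocount: float = 0.5) -> HaplogroupClassifier:
    return HaplogroupClassifier(level=level, pseudocount=pseudocount).fit(ds)


def predict_haplogroup(h: YHaplotype, profile: HaplogroupClassifier) -> Prediction:
    post = profile.predict_proba_haplotype(h)
    ranked = sorted(post.items(), key=lambda kv: (-kv[1], kv[0]))
    winner = ranked[0][0]
    margin = ranked[0][1] - (ranked[1][1] if len(ranked) > 1 else 0.0)
    return Prediction(posteriors=post, winner=winner, margin=margin)


@dataclass
class CVReport:
    accuracy: float
    per_class_recall: dict[str, float]
    confusion: pd.DataFrame
    excluded_classes: list[str]


def cross_validate(
    ds: PopulationDataset, level: int = 1, k: int = 5, seed: int = 0,
    pseudocount: float = 0.5,
) -> CVReport:
    """Stratified k-fold accuracy of the haplogroup classifier.

    Classes with fewer than k samples are excluded (with a record in the
    report); deterministic given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array(_labels_at_level(ds, level))
    counts = pd.Series(labels).value_counts()
    usable = sorted(counts[counts >= k].index)
    excluded = sorted(counts[counts < k].index)
    if len(usable) < 2:
        raise ValueError("fewer than 2 classes with enough samples")
    mask = np.isin(labels, usable)
    samples = [s for s, m in zip(ds.samples, mask) if m]
    y = labels[mask]
    sub = PopulationDataset(panel=ds.panel, samples=samples)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    idx = np.arange(len(y))
    for train_idx, test_idx in skf.split(idx, y):
        train_ds = PopulationDataset(panel=ds.panel, samples=[samples[i] for i in train_idx])
        clf = HaplogroupClassifier(level=level, pseudocount=pseudocount).fit(
            train_ds, y=[y[i] for i in train_idx]
        )
        for i in test_idx:
            y_pred[i] = predict_haplogroup(samples[i].haplotype, clf).winner
    acc = float(np.mean(y_pred == y))
    recall = {
        c: float(np.mean(y_pred[y == c] == c)) for c in usable
    }
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(y_pred, name="predicted"), dropna=False
    )
    return CVReport(accuracy=acc, per_class_recall=recall, confusion=confusion,
                    excluded_classes=excluded)


def save_profile(clf: HaplogroupClassifier, path: str | Path) -> None:
    rows = []
    for c in clf.classes_:
        for loc, freqs in clf.freq_[c].items():
            for a, f in sorted(freqs.items()):
                rows.append({"haplogroup": c, "locus": loc, "allele": a, "frequency": f})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
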