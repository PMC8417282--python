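"""The "spectral phenotype" decoding protocol.

Each lead contributes one feature vector: its session-averaged PSD
restricted to 1-50 Hz and renormalized to unit sum.  Four classes are
formed from (area x group): ACC-control, HPC-control, ACC-STZ, HPC-STZ.
The protocol trains a linear multi-class support vector machine
(one-vs-one ensemble) on a balanced random draw of leads per class and
classifies all held-out leads; repeating this over many draws yields
accuracy distributions, row-stochastic confusion matrices, mean posterior
probabilities per true class, and a breakdown of errors by whether the
group, the area, or both were wrong.  A label-permutation null establishes
the empirical chance level (25% for balanced classes), and grouped
leave-one-subject-out / leave-one-session-out designs test whether the
phenotype generalizes across animals and days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .session import LeadInfo
from .spectral import NORM_RANGE_DECODING, LeadSpectrum

CLASSES = ("ACC-control", "HPC-control", "ACC-STZ", "HPC-STZ")
DEFAULT_SIZES = tuple(range(5, 86, 10))  # 5, 15, ..., 85
MISCLASS_KINDS = ("correct", "wrong_group", "wrong_area", "wrong_both")


@dataclass
class PhenotypeDataset:
    """Per-lead normalized 1-50 Hz spectra with (area x group) labels."""

    features: np.ndarray          # [n_leads x n_freqs], rows sum to 1
    labels: np.ndarray            # strings from CLASSES
    subject_ids: np.ndarray
    session_ids: np.ndarray
    freqs: np.ndarray

    @property
    def n_leads(self) -> int:
        return self.features.shape[0]

    def class_indices(self) -> dict[str, np.ndarray]:
        return {c: np.flatnonzero(self.labels == c) for c in np.unique(self.labels)}


@dataclass
class DecodingResult:
    """Summary of one repeated train/test protocol."""

    accuracies: np.ndarray              # per iteration
    confusion: np.ndarray               # mean row-stochastic [n_class x n_class]
    posterior: np.ndarray | None        # mean P(class | true class), same shape
    misclass: dict[str, float]          # mean fraction per MISCLASS_KINDS
    classes: tuple[str, ...] = CLASSES

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def lead_label(lead: LeadInfo) -> str:
    return f"{lead.area}-{lead.group}"


def build_phenotype_dataset(
    spectra: list[LeadSpectrum],
    leads: list[LeadInfo],
    freq_range: tuple[float, float] = NORM_RANGE_DECODING,
) -> PhenotypeDataset:
    """Assemble the decoding feature matrix from per-lead session spectra.

    Spectra and lead metadata are matched by lead_id; features are
    restricted to ``freq_range`` and renormalized to unit sum per row.
    """
    by_id = {li.lead_id: li for li in leads}
    rows, labels, subjects, sessions = [], [], [], []
    freqs = None
    for sp in spectra:
        li = by_id.get(sp.lead_id)
        if li is None:
            raise ValueError(f"no lead metadata for spectrum {sp.lead_id!r}")
        keep = (sp.freqs >= freq_range[0]) & (sp.freqs <= freq_range[1])
        if not np.any(keep):
            raise ValueError(f"spectrum {sp.lead_id!r} has no bins in {freq_range}")
        f = sp.freqs[keep]
        if freqs is None:
            freqs = f
        elif not np.array_equal(freqs, f):
            raise ValueError("spectra have inconsistent frequency grids")
        v = sp.norm_power[keep]
        total = v.sum()
        if total <= 0:
            raise ValueError(f"spectrum {sp.lead_id!r} has zero mass in {freq_range}")
        rows.append(v / total)
        labels.append(lead_label(li))
        subjects.append(li.subject_id)
        sessions.append(li.session_id)
    return PhenotypeDataset(
        features=np.asarray(rows),
        labels=np.asarray(labels),
        subject_ids=np.asarray(subjects),
        session_ids=np.asarray(sessions),
        freqs=freqs,
    )


def _make_classifier(probability: bool, random_state: int):
    # linear kernel, C = 1, one-vs-one multi-class ensemble (SVC default);
    # posteriors come from Platt-style sigmoid calibration fitted on the
    # training set by internal cross-validation
    svc = SVC(kernel="linear", C=1.0, random_state=random_state)
    if probability:
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    return svc


def _misclass_kind(true: str, pred: str) -> str:
    if true == pred:
        return "correct"
    t_area, t_group = true.split("-")
    p_area, p_group = pred.split("-")
    if t_area == p_area:
        return "wrong_group"
    if t_group == p_group:
        return "wrong_area"
    return "wrong_both"


def _one_split(
    ds: PhenotypeDataset,
    labels: np.ndarray,
    size: int,
    rng: np.random.Generator,
    probability: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray]:
    """Balanced train draw, held-out predictions.

    Returns (test_true, test_pred, test_proba, test_idx).
    """
    classes = np.unique(labels)
    train_idx = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        if size >= members.size:
            raise ValueError(
                f"training size {size} needs fewer than the {members.size} leads of class {c!r}"
            )
        train_idx.append(rng.choice(members, size=size, replace=False))
    train_idx = np.concatenate(train_idx)
    mask = np.zeros(len(labels), dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    assert not np.intersect1d(train_idx, test_idx).size, "train/test sets overlap"
    clf = _make_classifier(probability, random_state=int(rng.integers(2**31 - 1)))
    clf.fit(ds.features[train_idx], labels[train_idx])
    pred = clf.predict(ds.features[test_idx])
    proba = None
    if probability:
        raw = clf.predict_proba(ds.features[test_idx])
        order = {c: i for i, c in enumerate(clf.classes_)}
        cols = [order[c] for c in classes]
        proba = raw[:, cols]
    return labels[test_idx], pred, proba, test_idx


def _summarize(
    trues: list[np.ndarray],
    preds: list[np.ndarray],
    probas: list[np.ndarray] | None,
    classes: tuple[str, ...],
) -> DecodingResult:
    k = len(classes)
    cidx = {c: i for i, c in enumerate(classes)}
    accs = np.empty(len(trues))
    conf = np.zeros((k, k))
    post = np.zeros((k, k)) if probas is not None else None
    post_n = np.zeros(k)
    mis = {kind: 0.0 for kind in MISCLASS_KINDS}
    for it, (t, p) in enumerate(zip(trues, preds)):
        accs[it] = float(np.mean(t == p))
        m = np.zeros((k, k))
        for ti, pi in zip(t, p):
            m[cidx[ti], cidx[pi]] += 1
            mis[_misclass_kind(ti, pi)] += 1.0 / t.size / len(trues)
        rows = m.sum(axis=1, keepdims=True)
        conf += np.divide(m, rows, out=np.zeros_like(m), where=rows > 0) / len(trues)
        if post is not None:
            pr = probas[it]
            for ci, c in enumerate(classes):
                sel = t == c
                if sel.any():
                    post[ci] += pr[sel].mean(axis=0)
                    post_n[ci] += 1
    if post is not None:
        post = post / np.maximum(post_n, 1)[:, None]
    return DecodingResult(
        accuracies=accs, confusion=conf, posterior=post, misclass=mis, classes=classes
    )


def training_size_sweep(
    ds: PhenotypeDataset,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    n_iter: int = 1000,
    seed: int = 0,
    posteriors: bool = True,
) -> dict[int, DecodingResult]:
    """Repeated balanced train/test splits at each training-set size."""
    classes = tuple(sorted(np.unique(ds.labels)))
    out = {}
    for size in sizes:
        rng = np.random.default_rng(np.random.SeedSequence([seed, size]))
        use_post = posteriors and size >= 3  # calibration needs 3 folds per class
        trues, preds, probas = [], [], ([] if use_post else None)
        for _ in range(n_iter):
            t, p, pr, _ = _one_split(ds, ds.labels, size, rng, use_post)
            trues.append(t)
            preds.append(p)
            if use_post:
                probas.append(pr)
        out[size] = _summarize(trues, preds, probas, classes)
    return out


def shuffled_null(
    ds: PhenotypeDataset,
    size: int = 85,
    n_iter: int = 1000,
    seed: int = 0,
) -> DecodingResult:
    """Label-permutation null: class labels shuffled before each split."""
    classes = tuple(sorted(np.unique(ds.labels)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9999]))
    trues, preds = [], []
    for _ in range(n_iter):
        labels = ds.labels[rng.permutation(ds.n_leads)]
        t, p, _, _ = _one_split(ds, labels, size, rng, probability=False)
        trues.append(t)
        preds.append(p)
    return _summarize(trues, preds, None, classes)


def leave_one_group_out(
    ds: PhenotypeDataset,
    group_key: str = "subject_id",
    per_class: int = 40,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out (or session-out) decoding accuracy per held-out unit.

    For each held-out unit, ``n_iter`` balanced training sets of
    ``per_class`` leads per class are drawn from the remaining units and
    all the held-out unit's leads classified; the mean fraction correctly
    assigned to (area x group) is reported per unit with its group label.
    """
    units = ds.subject_ids if group_key == "subject_id" else ds.session_ids
    rows = []
    for ui, unit in enumerate(sorted(np.unique(units))):
        held = units == unit
        rest = np.flatnonzero(~held)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, ui]))
        accs = np.empty(n_iter)
        for it in range(n_iter):
            train_idx = []
            for c in sorted(np.unique(ds.labels)):
                members = rest[ds.labels[rest] == c]
                if members.size < per_class:
                    raise ValueError(
                        f"holding out {unit!r} leaves only {members.size} leads of "
                        f"class {c!r}; need {per_class}"
                    )
                train_idx.append(rng.choice(members, size=per_class, replace=False))
            train_idx = np.concatenate(train_idx)
            assert not np.intersect1d(train_idx, np.flatnonzero(held)).size
            clf = _make_classifier(False, random_state=int(rng.integers(2**31 - 1)))
            clf.fit(ds.features[train_idx], ds.labels[train_idx])
            accs[it] = float(np.mean(clf.predict(ds.features[held]) == ds.labels[held]))
        group = str(ds.labels[held][0]).split("-")[1]
        rows.append(
            {
                "unit": unit,
                "group": group,
                "n_leads": int(held.sum()),
                "mean_accuracy": float(accs.mean()),
            }
        )
    return pd.DataFrame(rows)
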