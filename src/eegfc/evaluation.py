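"""Subject-wise cross-validation, baseline classifiers and reporting.

Fold construction never splits one subject's trials across the training,
validation and test sets; with two balanced groups of ``n_folds`` subjects,
fold i tests one subject from each group (sorted-ID pairing), validates on
the cyclically next pair, and trains on the rest — for 24+24 subjects that
is 44 training subjects per fold.  Classification is scored at the trial
level, pooled over folds, and the whole procedure is repeated (9 times by
default) with fresh weight initializations to report mean +/- sd accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .cnn import CNNConfig, build_model, evaluate, train
from .connectivity import ConnectivityMatrix
from .imaging import upper_triangle_vector


@dataclass(frozen=True)
class CVFold:
    """One subject-wise fold: test / validation / training subject sets."""

    index: int
    test_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    train_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = (set(self.test_subjects), set(self.val_subjects), set(self.train_subjects))
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError(f"fold {self.index}: subject appears in more than one set")


def make_subjectwise_folds(
    subject_ids: Sequence[str],
    group_labels: Sequence[str],
    n_folds: int = 24,
) -> list[CVFold]:
    """Deterministic paired folds over two balanced groups.

    Subjects are sorted by ID within each group; fold i tests pair i and
    validates on pair ``(i+1) mod n_folds``.  Test sets partition the cohort
    when each group has exactly ``n_folds`` subjects.
    """
    if len(subject_ids) != len(group_labels):
        raise ValueError("subject_ids and group_labels must align")
    groups: dict[str, list[str]] = {}
    for sid, g in zip(subject_ids, group_labels):
        groups.setdefault(g, []).append(sid)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(groups)}")
    per_group = [sorted(v) for _, v in sorted(groups.items())]
    if any(len(g) < n_folds for g in per_group):
        raise ValueError(
            f"each group needs >= {n_folds} subjects for {n_folds}-fold CV; "
            f"got sizes {[len(g) for g in per_group]}"
        )
    all_ids = set(subject_ids)
    folds = []
    for i in range(n_folds):
        test = tuple(g[i] for g in per_group)
        val = tuple(g[(i + 1) % n_folds] for g in per_group)
        train_ = tuple(sorted(all_ids - set(test) - set(val)))
        if not train_:
            raise ValueError(
                "empty training set: need more than 2 subjects per group "
                "(test and validation pairs consume two per fold)"
            )
        folds.append(CVFold(i, test, val, train_))
    return folds


# ---------------------------------------------------------------------------
# CNN cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Accuracy and ROC aggregates of repeated subject-wise CV."""

    accuracies: np.ndarray            # per repeat (trial-level, pooled folds)
    fold_accuracies: np.ndarray       # repeats x folds
    rocs: list[tuple[np.ndarray, np.ndarray, float]]  # per repeat (fpr, tpr, auc)
    metric: str = ""
    band: str = ""
    block: str = ""

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def _gather(images: Mapping[str, np.ndarray], labels: Mapping[str, int],
            subjects: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    xs = [np.asarray(images[s], dtype=np.float32) for s in subjects]
    ys = [np.full(len(images[s]), labels[s], dtype=np.int64) for s in subjects]
    return np.concatenate(xs), np.concatenate(ys)


def run_cv(
    images: Mapping[str, np.ndarray],
    labels: Mapping[str, int],
    folds: Sequence[CVFold],
    cnn_config: CNNConfig,
    repeats: int = 9,
    seed: int = 0,
    metric: str = "",
    band: str = "",
    block: str = "",
) -> CVResult:
    """Repeated subject-wise cross-validation of the CNN.

    ``images[subject]`` holds that subject's per-trial image stack
    (trials x side x side [x 3]); ``labels[subject]`` is the binary class.
    Each repeat re-initializes weights with a fresh derived seed, trains on
    every fold, and scores accuracy over the pooled test trials.
    """
    subjects = set().union(*( {*f.test_subjects, *f.val_subjects, *f.train_subjects}
                              for f in folds))
    missing = subjects - set(images)
    if missing:
        raise ValueError(f"images missing for subjects: {sorted(missing)[:5]}")
    for f in folds:  # structural leakage check
        overlap = (set(f.test_subjects) & set(f.train_subjects)) | (
            set(f.test_subjects) & set(f.val_subjects)
        ) | (set(f.val_subjects) & set(f.train_subjects))
        if overlap:
            raise ValueError(f"fold {f.index}: leakage via subjects {sorted(overlap)}")

    sample = np.asarray(next(iter(images.values())))
    side = sample.shape[1]
    acc_per_repeat = np.zeros(repeats)
    fold_acc = np.zeros((repeats, len(folds)))
    rocs = []
    for r in range(repeats):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0])
        y_true_all, p_pos_all = [], []
        n_correct = n_total = 0
        for f in folds:
            cfg = _dc_replace(cnn_config, seed=int(
                np.random.SeedSequence([rep_seed, f.index]).generate_state(1)[0]
            ) % (2**31))
            model = build_model(cfg, side=side)
            tr = _gather(images, labels, f.train_subjects)
            va = _gather(images, labels, f.val_subjects)
            te = _gather(images, labels, f.test_subjects)
            train(model, tr, va, cfg)
            res = evaluate(model, te[0], te[1])
            proba = model.predict_proba(te[0])
            y_true_all.append(te[1])
            p_pos_all.append(proba[:, 1])
            fold_acc[r, f.index] = res.accuracy
            n_correct += int(round(res.accuracy * len(te[1])))
            n_total += len(te[1])
        acc_per_repeat[r] = n_correct / n_total
        y_true = np.concatenate(y_true_all)
        p_pos = np.concatenate(p_pos_all)
        fpr, tpr, _ = _sk_roc_curve(y_true, p_pos)
        rocs.append((fpr, tpr, float(_sk_auc(fpr, tpr))))
    return CVResult(acc_per_repeat, fold_acc, rocs, metric=metric, band=band, block=block)


# ---------------------------------------------------------------------------
# baseline feature-vector classifiers
# ---------------------------------------------------------------------------

def mean_fc_features(
    matrices_by_band: Mapping[str, Sequence[ConnectivityMatrix | np.ndarray]],
) -> pd.DataFrame:
    """Per-trial scalar features: mean of the off-diagonal upper triangle.

    One column per band; N rows for N trials (N x 1 single band, N x 3 for a
    three-band stack).
    """
    cols = {}
    for band, mats in matrices_by_band.items():
        cols[band] = [float(upper_triangle_vector(m).mean()) for m in mats]
    df = pd.DataFrame(cols)
    if df.isna().any().any() or len(set(map(len, cols.values()))) > 1:
        raise ValueError("bands disagree on the number of trials")
    return df


def _baseline_zoo(seed: int) -> dict:
    return {
        "BN": GaussianNB(),
        "LR": LogisticRegression(max_iter=1000),
        "kNN-1": KNeighborsClassifier(n_neighbors=1),
        "kNN-5": KNeighborsClassifier(n_neighbors=5),
        "kNN-10": KNeighborsClassifier(n_neighbors=10),
        "RF": RandomForestClassifier(random_state=seed),
    }


def baseline_classifiers(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    subject_of_trial: Sequence[str],
    folds: Sequence[CVFold],
    seed: int = 0,
) -> pd.DataFrame:
    """Classic classifiers on mean-connectivity feature vectors.

    Four classifier families at default settings — naive Bayes (the
    BayesNet slot), logistic regression, kNN at k in {1, 5, 10}, random
    forest — evaluated on the same subject-wise folds as the CNN
    (validation subjects join the training split; these classifiers do no
    early stopping).  Returns per-classifier pooled accuracy plus the
    ``max`` row conventionally reported.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=int)
    subj = np.asarray(subject_of_trial)
    if np.unique(x).size == 1:
        warnings.warn("degenerate single-valued features", stacklevel=2)
    accs: dict[str, list[tuple[int, int]]] = {}
    for name, clf in _baseline_zoo(seed).items():
        counts = []
        for f in folds:
            tr_mask = np.isin(subj, f.train_subjects + f.val_subjects)
            te_mask = np.isin(subj, f.test_subjects)
            clf.fit(x[tr_mask], y[tr_mask])
            pred = clf.predict(x[te_mask])
            counts.append((int((pred == y[te_mask]).sum()), int(te_mask.sum())))
        accs[name] = counts
    rows = {
        name: sum(c for c, _ in counts) / sum(n for _, n in counts)
        for name, counts in accs.items()
    }
    table = pd.DataFrame({"accuracy": rows})
    table.loc["max"] = table["accuracy"].max()
    return table


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(results: Sequence[CVResult], outdir=None):
    """Tidy accuracy table and per-condition ROC figures.

    Each figure shows the per-repeat ROC curves as light traces with the
    vertically averaged mean curve on top.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        warnings.warn("no CV results to report", stacklevel=2)
        return pd.DataFrame(columns=["metric", "band", "block", "mean", "sd"]), {}

    rows = [
        {"metric": r.metric, "band": r.band, "block": r.block,
         "mean": r.mean, "sd": r.sd}
        for r in results
    ]
    table = pd.DataFrame(rows)

    figures = {}
    grid = np.linspace(0, 1, 101)
    for r in results:
        fig, ax = plt.subplots(figsize=(4, 4))
        tprs = []
        for fpr, tpr, auc_val in r.rocs:
            ax.plot(fpr, tpr, color="tab:blue", alpha=0.25, lw=0.8)
            tprs.append(np.interp(grid, fpr, tpr))
        mean_tpr = np.mean(tprs, axis=0)
        mean_auc = float(np.mean([a for *_, a in r.rocs]))
        ax.plot(grid, mean_tpr, color="tab:blue", lw=2,
                label=f"mean AUC = {mean_auc:.2f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        name = "_".join(filter(None, (r.metric, r.band, r.block))) or "condition"
        ax.set_title(name)
        ax.legend(loc="lower right", frameon=False)
        figures[name] = fig
        if outdir is not None:
            from pathlib import Path

            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            fig.savefig(outdir / f"roc_{name}.png", dpi=120)
            plt.close(fig)
    if outdir is not None:
        table.to_csv(Path(outdir) / "cv_accuracy.csv", index=False)
    return table, figures
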