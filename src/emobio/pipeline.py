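"""Feature aggregation, selection, and repeated-holdout classification.

The per-subject feature table averages every (feature, band) value over
the trials and channels of each electrode cluster, yielding
8 features x 5 bands x 4 clusters = 160 columns.  Each holdout repetition
re-ranks features by absolute Welch t on the training rows only, then
scores a linear SVM and a WiSARD on the held-out subjects for a grid of
feature counts.  Test rows never influence feature selection, encoder
fitting, or standardization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .bands import BAND_ORDER
from .features import FEATURES, WindowedFeatures
from .montage import Montage
from .wisard import WisardClassifier

__all__ = [
    "FeatureTable",
    "EvaluationReport",
    "cluster_average",
    "rank_features",
    "holdout_split",
    "evaluate",
    "metrics",
    "covariate_correlation",
    "report",
    "DEFAULT_K_GRID",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("svm_linear", "wisard")
DEFAULT_K_GRID = tuple(range(5, 165, 5))  # 5, 10, ..., 160
DEFAULT_METRICS_K = 15
POSITIVE_CLASS = "asd"  # positive class for sensitivity / precision


def feature_key(feature: str, band: str, cluster: str) -> str:
    return f"{feature}__{band}__{cluster}"


@dataclass
class FeatureTable:
    """Subjects x feature-key matrix with group labels and covariates."""

    features: pd.DataFrame  # index: subject; columns: feature__band__cluster
    groups: pd.Series  # index: subject
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.features.index.duplicated().any():
            raise ValueError("duplicated subjects in feature table")
        if not self.features.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.features.index)
        if self.groups.isna().any():
            raise ValueError("missing group label for some subjects")

    @property
    def subjects(self) -> list:
        return list(self.features.index)

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    def subset(self, subjects) -> "FeatureTable":
        cov = self.covariates.loc[subjects] if self.covariates is not None else None
        return FeatureTable(
            features=self.features.loc[subjects],
            groups=self.groups.loc[subjects],
            covariates=cov,
        )

    def to_csv(self, path) -> None:
        out = self.features.copy()
        out.insert(0, "group", self.groups)
        if self.covariates is not None:
            for c in self.covariates.columns:
                out.insert(1, c, self.covariates[c])
        out.to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path, covariate_columns: tuple[str, ...] = ()) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject")
        groups = df.pop("group")
        cov = df[list(covariate_columns)] if covariate_columns else None
        feats = df.drop(columns=list(covariate_columns), errors="ignore")
        return cls(features=feats, groups=groups, covariates=cov)


def cluster_average(
    wf: WindowedFeatures,
    montage: Montage,
    window: str,
    groups: dict[str, str] | None = None,
) -> FeatureTable:
    """Per-subject mean over (trial, channel-in-cluster) for one window.

    NaN sentinels are skipped (with a log of how many); subjects with no
    valid value at all are excluded with a warning.  Exactly
    ``len(FEATURES) * len(BAND_ORDER) * len(clusters)`` columns come back,
    NaN where a subject had no defined value for a key.
    """
    t = wf.table
    t = t[t["window"] == window]
    if t.empty:
        raise ValueError(f"no rows for window {window!r}")
    chan_to_cluster = {
        c: cid for cid, chans in montage.clusters.items() for c in chans
    }
    t = t[t["channel"].isin(chan_to_cluster)].copy()
    t["cluster"] = t["channel"].map(chan_to_cluster)
    n_nan = int(t["value"].isna().sum())
    if n_nan:
        logger.info("cluster_average: skipping %d NaN sentinel value(s)", n_nan)

    agg = t.groupby(["subject", "feature", "band", "cluster"])["value"].mean()
    wide = agg.unstack(["feature", "band", "cluster"])
    keys = [
        (f, b, c)
        for f in FEATURES
        for b in BAND_ORDER
        for c in montage.clusters
    ]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(keys))
    wide.columns = [feature_key(*k) for k in keys]

    empty = wide.isna().all(axis=1)
    if empty.any():
        warnings.warn(
            f"excluding subject(s) with no valid trials: {list(wide.index[empty])}",
            stacklevel=2,
        )
        wide = wide[~empty]

    if groups is None:
        grp = pd.Series("unknown", index=wide.index)
    else:
        grp = pd.Series({s: groups[s] for s in wide.index})
    return FeatureTable(features=wide, groups=grp)


def rank_features(train: FeatureTable) -> pd.DataFrame:
    """Welch two-sample t per column on training rows; descending ``|t|``.

    Ties (and NaN t-values) fall back to the fixed column order.  Returns a
    DataFrame with columns ``feature_key``, ``t``, ``abs_t`` in rank order.
    """
    labels = sorted(train.groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = train.features[train.groups == labels[0]]
    b = train.features[train.groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 training rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = stats.ttest_ind(a, b, equal_var=False, nan_policy="omit").statistic
    tvals = np.asarray(tvals, dtype=float)
    abs_t = np.abs(tvals)
    order = np.argsort(np.where(np.isnan(abs_t), -np.inf, abs_t) * -1, kind="stable")
    return pd.DataFrame(
        {
            "feature_key": train.features.columns[order],
            "t": tvals[order],
            "abs_t": abs_t[order],
        }
    ).reset_index(drop=True)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def holdout_split(
    table: FeatureTable, train_frac: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified random train/test partition of subjects."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_subj: list = []
    test_subj: list = []
    for label in sorted(table.groups.unique()):
        subj = np.asarray(table.groups.index[table.groups == label])
        if len(subj) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 subjects")
        perm = rng.permutation(len(subj))
        n_train = _round_half_up(train_frac * len(subj))
        n_train = min(max(n_train, 1), len(subj) - 1)  # keep both sides non-empty
        train_subj.extend(subj[perm[:n_train]])
        test_subj.extend(subj[perm[n_train:]])
    # restore table order for determinism independent of group interleaving
    order = {s: i for i, s in enumerate(table.subjects)}
    train_subj.sort(key=order.__getitem__)
    test_subj.sort(key=order.__getitem__)
    return table.subset(train_subj), table.subset(test_subj)


def metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Binary classification metrics; zero-denominator ratios are NaN."""
    if min(tp, tn, fp, fn) < 0 or tp + tn + fp + fn == 0:
        raise ValueError("counts must be non-negative with a positive total")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "specificity": ratio(tn, tn + fp),
        "sensitivity": recall,
        "precision": precision,
        "f1": (
            2 * precision * recall / (precision + recall)
            if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0
            else float("nan")
        ),
    }


def _fit_predict(name: str, Xtr, ytr, Xte, seed: int, standardize: bool) -> np.ndarray:
    if name == "svm_linear":
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(Xtr, ytr)
        return clf.predict(Xte)
    if name == "wisard":
        w = WisardClassifier(seed=seed)
        w.fit(Xtr, ytr)
        return w.predict(Xte)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class EvaluationReport:
    """Per-repetition accuracies, headline metrics, and selection tallies."""

    accuracy: pd.DataFrame  # columns: run, classifier, k, rep, accuracy
    metrics_table: pd.DataFrame  # columns: run, classifier, metric, mean, sem
    selections: pd.DataFrame  # columns: run, classifier, rep, feature_key (top metrics_k)
    metrics_k: int
    reps: int
    contrast: pd.DataFrame | None = None  # columns: classifier, k, t, p, p_fdr

    def summary(self) -> pd.DataFrame:
        g = self.accuracy.groupby(["run", "classifier", "k"])["accuracy"]
        out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1)).reset_index()
        out["sem"] = out["sd"] / np.sqrt(self.reps)
        return out.drop(columns="sd")

    def tallies(self, by: str) -> pd.DataFrame:
        """Top-feature selection counts grouped by 'band' or 'cluster'."""
        if by not in ("band", "cluster"):
            raise ValueError("by must be 'band' or 'cluster'")
        idx = {"feature": 0, "band": 1, "cluster": 2}[by]
        sel = self.selections.copy()
        sel[by] = sel["feature_key"].str.split("__").str[idx]
        return (
            sel.groupby(["run", "classifier", by])
            .size()
            .rename("count")
            .reset_index()
        )


def _evaluate_single_run(
    table: FeatureTable,
    classifiers: tuple[str, ...],
    k_grid: tuple[int, ...],
    reps: int,
    rep_seeds: list[int],
    train_frac: float,
    metrics_k: int,
    standardize: bool,
):
    acc_rows, sel_rows, conf = [], [], {c: [] for c in classifiers}
    for rep in range(reps):
        rs = rep_seeds[rep]
        tr, te = holdout_split(table, train_frac, rs)
        ranking = rank_features(tr)["feature_key"].to_numpy()
        ytr = tr.groups.to_numpy(dtype=str)
        yte = te.groups.to_numpy(dtype=str)
        for k in k_grid:
            cols = ranking[:k]
            Xtr = tr.features[cols].to_numpy()
            Xte = te.features[cols].to_numpy()
            for name in classifiers:
                pred = _fit_predict(name, Xtr, ytr, Xte, seed=rs, standardize=standardize)
                acc_rows.append((name, int(k), rep, float(np.mean(pred == yte))))
                if k == metrics_k:
                    pos, neg = POSITIVE_CLASS, None
                    tp = int(np.sum((pred == pos) & (yte == pos)))
                    fp = int(np.sum((pred == pos) & (yte != pos)))
                    fn = int(np.sum((pred != pos) & (yte == pos)))
                    tn = int(np.sum((pred != pos) & (yte != pos)))
                    conf[name].append((tp, tn, fp, fn))
        for name in classifiers:
            for fk in ranking[:metrics_k]:
                sel_rows.append((name, rep, fk))
    return acc_rows, sel_rows, conf


def evaluate(
    table: FeatureTable,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    reps: int = 50,
    seed: int = 0,
    neutral_table: FeatureTable | None = None,
    train_frac: float = 0.8,
    metrics_k: int = DEFAULT_METRICS_K,
    standardize: bool = True,
) -> EvaluationReport:
    """Repeated stratified holdout with per-repetition feature ranking.

    When ``neutral_table`` is given it is evaluated with the same
    per-repetition splits and a paired per-k emotion-vs-neutral accuracy
    contrast (FDR-corrected) is attached to the report.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_cols = table.features.shape[1]
    if any(k < 1 or k > n_cols for k in k_grid):
        raise ValueError(f"k_grid entries must lie in [1, {n_cols}]")
    if metrics_k not in k_grid:
        raise ValueError("metrics_k must be in k_grid")
    rep_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(reps)]

    runs = {"emotion": table}
    if neutral_table is not None:
        if list(neutral_table.subjects) != list(table.subjects):
            raise ValueError("emotion and neutral tables must share subjects")
        runs["neutral"] = neutral_table

    acc_frames, sel_frames, met_rows = [], [], []
    for run, tbl in runs.items():
        acc_rows, sel_rows, conf = _evaluate_single_run(
            tbl, classifiers, tuple(k_grid), reps, rep_seeds, train_frac, metrics_k,
            standardize,
        )
        a = pd.DataFrame(acc_rows, columns=["classifier", "k", "rep", "accuracy"])
        a.insert(0, "run", run)
        acc_frames.append(a)
        s = pd.DataFrame(sel_rows, columns=["classifier", "rep", "feature_key"])
        s.insert(0, "run", run)
        sel_frames.append(s)
        for name in classifiers:
            per_rep = pd.DataFrame([metrics(*c) for c in conf[name]])
            for metric in per_rep.columns:
                vals = per_rep[metric].dropna()
                met_rows.append(
                    (
                        run,
                        name,
                        metric,
                        float(vals.mean()) if len(vals) else float("nan"),
                        float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                    )
                )

    accuracy = pd.concat(acc_frames, ignore_index=True)
    selections = pd.concat(sel_frames, ignore_index=True)
    metrics_table = pd.DataFrame(
        met_rows, columns=["run", "classifier", "metric", "mean", "sem"]
    )

    contrast = None
    if neutral_table is not None:
        rows = []
        for name in classifiers:
            for k in k_grid:
                sub = accuracy[(accuracy["classifier"] == name) & (accuracy["k"] == k)]
                emo = sub[sub["run"] == "emotion"].sort_values("rep")["accuracy"].to_numpy()
                neu = sub[sub["run"] == "neutral"].sort_values("rep")["accuracy"].to_numpy()
                diff = emo - neu
                if np.allclose(diff.std(ddof=1), 0):
                    t, p = float("nan"), float("nan")
                else:
                    t, p = stats.ttest_rel(emo, neu)
                rows.append((name, int(k), float(t), float(p)))
        contrast = pd.DataFrame(rows, columns=["classifier", "k", "t", "p"])
        contrast["p_fdr"] = np.nan
        for name in classifiers:
            mask = (contrast["classifier"] == name) & contrast["p"].notna()
            if mask.any():
                contrast.loc[mask, "p_fdr"] = multipletests(
                    contrast.loc[mask, "p"], method="fdr_bh"
                )[1]

    return EvaluationReport(
        accuracy=accuracy,
        metrics_table=metrics_table,
        selections=selections,
        metrics_k=metrics_k,
        reps=reps,
        contrast=contrast,
    )


def covariate_correlation(
    table: FeatureTable, covariates: pd.DataFrame | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson r and two-sided p per (feature, covariate) pair, with FDR.

    Constant covariates (or features) give NaN sentinels rather than 0.
    """
    cov = covariates if covariates is not None else table.covariates
    if cov is None:
        raise ValueError("no covariates provided")
    cov = cov.reindex(table.features.index)
    rows = []
    for cname in cov.columns:
        y = cov[cname].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"covariate {cname!r} has fewer than 3 values")
        for fk in table.features.columns:
            x = table.features[fk].to_numpy(dtype=float)[ok]
            yy = y[ok]
            if np.ptp(x) == 0 or np.ptp(yy) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, yy)
            rows.append((fk, cname, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["feature_key", "covariate", "r", "p"])
    out["significant_uncorrected"] = out["p"] < alpha
    out["p_fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant_fdr"] = out["p_fdr"] < alpha
    return out


def report(ev: EvaluationReport, out_dir) -> list[str]:
    """Write accuracy curves, selection histograms, and CSV summaries.

    Returns the list of files written (paths as strings); output is
    deterministic for a fixed report.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save_csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(str(p))

    save_csv(ev.accuracy, "accuracy_per_rep.csv")
    save_csv(ev.summary(), "accuracy_summary.csv")
    save_csv(ev.metrics_table, f"metrics_k{ev.metrics_k}.csv")
    save_csv(ev.selections, "top_feature_selections.csv")
    meta = out / "report_meta.json"
    meta.write_text(
        json.dumps({"metrics_k": ev.metrics_k, "reps": ev.reps}), encoding="utf-8"
    )
    written.append(str(meta))
    save_csv(ev.tallies("band"), "top_feature_tallies_band.csv")
    save_csv(ev.tallies("cluster"), "top_feature_tallies_cluster.csv")
    if ev.contrast is not None:
        save_csv(ev.contrast, "emotion_vs_neutral_contrast.csv")

    summary = ev.summary()
    classifiers = sorted(summary["classifier"].unique())
    fig, axes = plt.subplots(1, len(classifiers), figsize=(6 * len(classifiers), 4),
                             squeeze=False)
    colors = {"emotion": "tab:blue", "neutral": "tab:orange"}
    for ax, name in zip(axes[0], classifiers):
        for run in sorted(summary["run"].unique()):
            sub = summary[(summary["classifier"] == name) & (summary["run"] == run)]
            ax.errorbar(sub["k"], sub["mean"], yerr=sub["sem"], label=run,
                        color=colors.get(run), capsize=2)
        ax.set_xlabel("number of features")
        ax.set_ylabel("test accuracy")
        ax.set_title(name)
        ax.axhline(0.5, color="gray", lw=0.5, ls="--")
        ax.legend()
    fig.tight_layout()
    p = out / "accuracy_vs_k.png"
    fig.savefig(p, metadata={"Software": None})
    plt.close(fig)
    written.append(str(p))

    for by in ("band", "cluster"):
        tal = ev.tallies(by)
        fig, axes = plt.subplots(1, len(classifiers), figsize=(5 * len(classifiers), 3.5),
                                 squeeze=False)
        for ax, name in zip(axes[0], classifiers):
            sub = tal[tal["classifier"] == name]
            piv = sub.pivot_table(index=by, columns="run", values="count",
                                  aggfunc="sum", fill_value=0)
            piv.plot.bar(ax=ax, color=[colors.get(r) for r in piv.columns])
            ax.set_title(f"{name}: top-{ev.metrics_k} selections by {by}")
            ax.set_ylabel("count")
        fig.tight_layout()
        p = out / f"top_feature_hist_{by}.png"
        fig.savefig(p, metadata={"Software": None})
        plt.close(fig)
        written.append(str(p))
    return written


def load_report(report_dir) -> EvaluationReport:
    """Rebuild an :class:`EvaluationReport` from a directory written by :func:`report`."""
    from pathlib import Path

    d = Path(report_dir)
    meta = json.loads((d / "report_meta.json").read_text(encoding="utf-8"))
    accuracy = pd.read_csv(d / "accuracy_per_rep.csv")
    selections = pd.read_csv(d / "top_feature_selections.csv")
    metrics_table = pd.read_csv(d / f"metrics_k{meta['metrics_k']}.csv")
    contrast_path = d / "emotion_vs_neutral_contrast.csv"
    contrast = pd.read_csv(contrast_path) if contrast_path.exists() else None
    return EvaluationReport(
        accuracy=accuracy,
        metrics_table=metrics_table,
        selections=selections,
        metrics_k=meta["metrics_k"],
        reps=meta["reps"],
        contrast=contrast,
    )
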