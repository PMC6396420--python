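"""Machine-learning recalibration of fetal genotype calls.

A per-category Random Forest learns, from families with known fetal truth,
which calls tend to be wrong, using features the Bayesian caller does not model
directly: depth, allelic balance, per-allele fragment-length and quality
summaries, pairing, plus the caller's own posteriors, log-likelihoods and
called genotype.  The output score per variant (probability the call is
correct) supports filtering at a chosen threshold, e.g. 0.7.

Training pools follow the scheme that worked on real families: SNP models for
maternal-only and double-het sites train within category; the paternal-only SNP
model trains on SNPs from all three categories (its own error rate is too low);
indel models train on SNPs + indels of the same category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .bayes import FIXED, PosteriorResult
from .fetal_fraction import FetalFractionProfile
from .sites import CALLING_CATEGORIES, Category, VariantSite, VarType
from .store import ALT, EvidenceStore, FragmentObservation

FEATURE_SCHEMA_VERSION = 1

FEATURE_COLUMNS = (
    "var_type_snp",
    "cat_maternal_only",
    "cat_paternal_only",
    "cat_double_het",
    "cat_fetal_informative",
    "gm_0", "gm_1", "gm_2",
    "gf_0", "gf_1", "gf_2",
    "depth",
    "n_ref",
    "n_alt",
    "allelic_balance",
    "ref_present",
    "alt_present",
    "ref_tlen_mean",
    "ref_tlen_sd",
    "alt_tlen_mean",
    "alt_tlen_sd",
    "frac_improper",
    "ref_baseq_mean",
    "alt_baseq_mean",
    "ref_mapq_mean",
    "alt_mapq_mean",
    "q00", "q01", "q11",
    "ll00", "ll01", "ll11",
    "called_00", "called_01", "called_11",
    "prior_entropy",
    "posterior_entropy",
    "max_posterior",
    "total_ff",
    "ff_mode_fixed",
)

_CAT_COLS = {
    Category.MATERNAL_ONLY_HET: "cat_maternal_only",
    Category.PATERNAL_ONLY_HET: "cat_paternal_only",
    Category.DOUBLE_HET: "cat_double_het",
    Category.FETAL_INFORMATIVE: "cat_fetal_informative",
}


class SchemaMismatchError(ValueError):
    pass


def _entropy(p) -> float:
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _allele_side(obs: list[FragmentObservation], allele: str) -> dict:
    """Per-allele summary features with zero-imputation and a presence flag."""
    sub = [o for o in obs if o.allele == allele]
    key = "ref" if allele != ALT else "alt"
    if not sub:
        return {
            f"{key}_present": 0.0,
            f"{key}_tlen_mean": 0.0,
            f"{key}_tlen_sd": 0.0,
            f"{key}_baseq_mean": 0.0,
            f"{key}_mapq_mean": 0.0,
        }
    tl = np.array([o.tlen for o in sub], dtype=float)
    return {
        f"{key}_present": 1.0,
        f"{key}_tlen_mean": float(tl.mean()),
        f"{key}_tlen_sd": float(tl.std()),
        f"{key}_baseq_mean": float(np.mean([o.base_quality for o in sub])),
        f"{key}_mapq_mean": float(np.mean([o.map_quality for o in sub])),
    }


def extract_features(
    site: VariantSite,
    observations: list[FragmentObservation],
    result: PosteriorResult,
    profile: FetalFractionProfile,
) -> dict:
    """Deterministic feature dict for one called site (schema above)."""
    if result.site_id != site.site_id:
        raise ValueError(f"result {result.site_id} does not match site {site.site_id}")
    n_ref = sum(1 for o in observations if o.allele != ALT)
    n_alt = len(observations) - n_ref
    row = {c: 0.0 for c in FEATURE_COLUMNS}
    row["var_type_snp"] = 1.0 if site.var_type is VarType.SNP else 0.0
    row[_CAT_COLS[site.category]] = 1.0
    row[f"gm_{site.g_mother}"] = 1.0
    row[f"gf_{site.g_father}"] = 1.0
    row["depth"] = float(len(observations))
    row["n_ref"] = float(n_ref)
    row["n_alt"] = float(n_alt)
    row["allelic_balance"] = n_alt / len(observations) if observations else 0.0
    row.update(_allele_side(observations, "REF"))
    row.update(_allele_side(observations, ALT))
    row["frac_improper"] = (
        float(np.mean([not o.properly_paired for o in observations])) if observations else 0.0
    )
    row["q00"], row["q01"], row["q11"] = result.posteriors
    row["ll00"], row["ll01"], row["ll11"] = result.log_likelihoods
    row[f"called_{('00', '01', '11')[result.called]}"] = 1.0
    row["prior_entropy"] = _entropy(result.prior)
    row["posterior_entropy"] = _entropy(result.posteriors)
    row["max_posterior"] = float(result.max_posterior)
    row["total_ff"] = float(profile.total_ff)
    row["ff_mode_fixed"] = 1.0 if result.ff_mode == FIXED else 0.0
    return row


def extract_feature_table(
    sites: list[VariantSite],
    store: EvidenceStore,
    results: list[PosteriorResult],
    profile: FetalFractionProfile,
) -> pd.DataFrame:
    """Feature matrix for many calls; carries site_id/category/var_type metadata columns."""
    site_by_id = {s.site_id: s for s in sites}
    rows = []
    for res in results:
        site = site_by_id[res.site_id]
        row = extract_features(site, store.observations(res.site_id), res, profile)
        row["site_id"] = res.site_id
        row["category"] = site.category.value
        row["var_type"] = site.var_type.value
        row["called"] = res.called
        rows.append(row)
    df = pd.DataFrame(
        rows, columns=list(FEATURE_COLUMNS) + ["site_id", "category", "var_type", "called"]
    )
    return df


@dataclass
class RecalibrationModel:
    """Trained per-category call-correctness classifier."""

    category: str
    var_type: str
    classifier: RandomForestClassifier
    schema_version: int = FEATURE_SCHEMA_VERSION
    feature_columns: tuple = FEATURE_COLUMNS
    provenance: dict = field(default_factory=dict)
    label_definition: str = "call_correct"


def _strategy_mask(table: pd.DataFrame, category: str, var_type: str, strategy: str) -> pd.Series:
    cats = {c.value for c in CALLING_CATEGORIES}
    if strategy == "within":
        return (table["category"] == category) & (table["var_type"] == var_type)
    if strategy != "paper":
        raise ValueError(f"unknown training strategy: {strategy}")
    if var_type == VarType.INDEL.value:
        # indels are sparse: pool SNPs + indels of the same category
        return table["category"] == category
    if category == Category.PATERNAL_ONLY_HET.value:
        # errors too rare within category: pool SNPs from all three categories
        return table["category"].isin(cats) & (table["var_type"] == VarType.SNP.value)
    return (table["category"] == category) & (table["var_type"] == VarType.SNP.value)


def train(
    table: pd.DataFrame,
    correct: np.ndarray,
    category: str,
    strategy: str = "paper",
    seed: int = 0,
    var_type: str = "SNP",
    n_estimators: int = 300,
    holdout: float = 0.25,
) -> RecalibrationModel:
    """Train the recalibration model for one (category, var_type).

    ``table`` is a feature table from :func:`extract_feature_table` covering the
    training families; ``correct`` are aligned booleans (call == truth).  Rows
    are pooled per the strategy, 75% train / 25% held out (stratified, seeded),
    and the held-out AUC is recorded in the model provenance.  Class imbalance
    is handled by class weighting.
    """
    correct = np.asarray(correct, dtype=bool)
    mask = _strategy_mask(table, category, var_type, strategy).to_numpy()
    X = table.loc[mask, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = correct[mask]
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"cannot train for {category}/{var_type}: labels are single-class "
            f"({y.sum()}/{len(y)} correct)"
        )
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=holdout, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        class_weight="balanced",
        min_samples_leaf=2,
        n_jobs=1,
    )
    clf.fit(X_tr, y_tr)
    ho_auc = None
    if len(np.unique(y_ho)) == 2:
        ho_auc = float(roc_auc_score(y_ho, clf.predict_proba(X_ho)[:, list(clf.classes_).index(True)]))
    return RecalibrationModel(
        category=category,
        var_type=var_type,
        classifier=clf,
        provenance={
            "strategy": strategy,
            "seed": seed,
            "n_train": int(len(y_tr)),
            "n_holdout": int(len(y_ho)),
            "holdout_auc": ho_auc,
        },
    )


def apply(model: RecalibrationModel, table: pd.DataFrame) -> np.ndarray:
    """Score calls: P(call is correct) per row, deterministic given the model."""
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise SchemaMismatchError(
            f"model schema v{model.schema_version} vs library v{FEATURE_SCHEMA_VERSION}"
        )
    missing = [c for c in model.feature_columns if c not in table.columns]
    if missing:
        raise SchemaMismatchError(f"feature table missing columns: {missing}")
    X = table[list(model.feature_columns)].to_numpy(dtype=float)
    col = list(model.classifier.classes_).index(True)
    return model.classifier.predict_proba(X)[:, col]


def filter_by_score(
    results: list[PosteriorResult],
    scores: np.ndarray,
    tau: float,
    sites: list[VariantSite] | None = None,
    truth: dict[str, int] | None = None,
):
    """Keep calls with recalibration score >= tau.

    Returns ``(kept_results, report)``; the report gives retained counts (per
    category when sites are supplied) and retained-subset accuracy when truth
    is supplied.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(results):
        raise ValueError("scores and results are misaligned")
    keep = scores >= tau
    kept = [r for r, k in zip(results, keep) if k]
    report: dict = {"tau": tau, "n_input": len(results), "n_retained": len(kept)}
    if sites is not None:
        cat_by_id = {s.site_id: s.category.value for s in sites}
        per_cat: dict[str, dict] = {}
        for r, k in zip(results, keep):
            cat = cat_by_id.get(r.site_id, "UNKNOWN")
            d = per_cat.setdefault(cat, {"retained": 0, "total": 0, "correct": 0})
            d["total"] += 1
            if k:
                d["retained"] += 1
                if truth is not None and r.called == truth[r.site_id]:
                    d["correct"] += 1
        for cat, d in per_cat.items():
            if truth is not None and d["retained"]:
                d["accuracy"] = d["correct"] / d["retained"]
        report["per_category"] = per_cat
    if truth is not None:
        if kept:
            report["accuracy"] = float(np.mean([r.called == truth[r.site_id] for r in kept]))
        report["accuracy_unfiltered"] = float(
            np.mean([r.called == truth[r.site_id] for r in results])
        )
    return kept, report


def save_model(model: RecalibrationModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> RecalibrationModel:
    model = joblib.load(path)
    if not isinstance(model, RecalibrationModel):
        raise SchemaMismatchError(f"{path} does not contain a RecalibrationModel")
    return model
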