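"""Composition models turning module score differences into effects.

The central quantity is the per-module score difference
``dS = S_alt - S_ref``. A nine-parameter robust linear model (intercept,
five dS terms, three indicator-times-dS interaction terms for regions
scored by two modules) predicts the change of logit(PSI) for exon
skipping; the same design with an allelic log-ratio response models
splicing-efficiency changes, and a logistic regression over the same
features classifies variant pathogenicity. Interaction terms keep the
effect of a variant that falls inside two scored windows from being
counted twice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .neural_modules import ScoringModule
from .variant_mapping import VariantExonPair, WindowSpec, overlap_indicators, split_region

PSI_CLIP = 1e-5  # PSI values are clipped to [PSI_CLIP, 1 - PSI_CLIP] before logit

FEATURE_NAMES = (
    "dS_intron3p",
    "dS_acceptor",
    "dS_exon",
    "dS_donor",
    "dS_intron5p",
    "ind_exon_ss:dS_exon",
    "ind_intron5p_donor:dS_intron5p",
    "ind_intron3p_acceptor:dS_intron3p",
)

REF_SCORE_NAMES = ("S_ref_intron3p", "S_ref_acceptor", "S_ref_exon", "S_ref_donor", "S_ref_intron5p")

PURPOSES = ("delta_logit_psi", "splicing_efficiency_invivo", "splicing_efficiency_invitro", "pathogenicity")


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out if out.ndim else float(out)


def logit(p):
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires values strictly inside (0, 1); clip first")
    out = np.log(p / (1.0 - p))
    return out if out.ndim else float(out)


def clip_psi(p):
    """Clip PSI into [1e-5, 1 - 1e-5] so the logit stays finite."""
    p = np.asarray(p, dtype=np.float64)
    out = np.clip(p, PSI_CLIP, 1.0 - PSI_CLIP)
    return out if out.ndim else float(out)


@dataclass
class ModuleDeltaScores:
    """The five dS values plus the three overlap indicators.

    Optionally carries the reference-allele scores, used by the extended
    pathogenicity feature set.
    """

    dS_intron3p: float
    dS_acceptor: float
    dS_exon: float
    dS_donor: float
    dS_intron5p: float
    ind_exon_ss: int
    ind_intron5p_donor: int
    ind_intron3p_acceptor: int
    ref_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("dS_intron3p", "dS_acceptor", "dS_exon", "dS_donor", "dS_intron5p"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")
        for name in ("ind_exon_ss", "ind_intron5p_donor", "ind_intron3p_acceptor"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    def features(self, feature_set: str = "delta") -> np.ndarray:
        base = np.array([
            self.dS_intron3p,
            self.dS_acceptor,
            self.dS_exon,
            self.dS_donor,
            self.dS_intron5p,
            self.ind_exon_ss * self.dS_exon,
            self.ind_intron5p_donor * self.dS_intron5p,
            self.ind_intron3p_acceptor * self.dS_intron3p,
        ])
        if feature_set == "delta":
            return base
        if feature_set == "extended":
            if not self.ref_scores:
                raise ValueError("extended feature set requires reference-allele scores")
            refs = np.array([self.ref_scores[k] for k in ("intron3p", "acceptor", "exon", "donor", "intron5p")])
            return np.concatenate([base, refs])
        raise ValueError(f"unknown feature set {feature_set!r}")


def feature_matrix(rows: Sequence[ModuleDeltaScores], feature_set: str = "delta") -> np.ndarray:
    return np.stack([r.features(feature_set) for r in rows])


def module_delta_scores(
    pair: VariantExonPair,
    modules: Mapping[str, ScoringModule],
    exon_head: str = "exon5p",
    windows: WindowSpec = WindowSpec(),
) -> ModuleDeltaScores:
    """Score ref and alt regions with the five modules and difference them.

    ``exon_head`` selects which exon module scores the exonic segment
    (the 5' head by default, which tracks exon skipping best). The
    acceptor-side intron is scored by the intron 3' module and the
    donor-side intron by the intron 5' module.
    """
    if not pair.filled:
        raise ValueError("pair regions are unfilled; call apply_variant first")
    if exon_head not in ("exon5p", "exon3p"):
        raise ValueError("exon_head must be 'exon5p' or 'exon3p'")
    ref_parts = split_region(pair.ref_region, windows)
    alt_parts = split_region(pair.alt_region, windows)
    assignment = {
        "intron3p": modules["intron3p"],
        "acceptor": modules["acceptor"],
        "exon": modules[exon_head],
        "donor": modules["donor"],
        "intron5p": modules["intron5p"],
    }
    ref_s = {part: mod.score(ref_parts[part]) for part, mod in assignment.items()}
    alt_s = {part: mod.score(alt_parts[part]) for part, mod in assignment.items()}
    ind_exon, ind_don, ind_acc = overlap_indicators(pair.variant, pair.exon, windows)
    return ModuleDeltaScores(
        dS_intron3p=alt_s["intron3p"] - ref_s["intron3p"],
        dS_acceptor=alt_s["acceptor"] - ref_s["acceptor"],
        dS_exon=alt_s["exon"] - ref_s["exon"],
        dS_donor=alt_s["donor"] - ref_s["donor"],
        dS_intron5p=alt_s["intron5p"] - ref_s["intron5p"],
        ind_exon_ss=ind_exon,
        ind_intron5p_donor=ind_don,
        ind_intron3p_acceptor=ind_acc,
        ref_scores=ref_s,
    )


@dataclass
class EffectModel:
    """Fitted coefficients of one composition model.

    For linear purposes ``coef`` holds the intercept followed by the
    eight feature weights (nine parameters in total); for pathogenicity
    it holds the logistic intercept and weights of the chosen feature
    set.
    """

    purpose: str
    coef: np.ndarray
    feature_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.purpose not in PURPOSES:
            raise ValueError(f"unknown purpose {self.purpose!r}")
        self.coef = np.asarray(self.coef, dtype=np.float64)
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite coefficients")
        if self.coef.size != len(self.feature_names) + 1:
            raise ValueError("coefficient count does not match feature design")

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def predict(self, rows: Sequence[ModuleDeltaScores] | np.ndarray) -> np.ndarray:
        if isinstance(rows, np.ndarray):
            X = rows
        else:
            fs = "extended" if len(self.feature_names) > len(FEATURE_NAMES) else "delta"
            X = feature_matrix(rows, fs)
        return self.coef[0] + X @ self.coef[1:]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "purpose": self.purpose,
            "coef": self.coef.tolist(),
            "feature_names": list(self.feature_names),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EffectModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            purpose=payload["purpose"],
            coef=np.array(payload["coef"]),
            feature_names=tuple(payload["feature_names"]),
            meta=payload.get("meta", {}),
        )


def fit_effect_model(
    rows: Sequence[ModuleDeltaScores],
    response: np.ndarray,
    purpose: str = "delta_logit_psi",
    huber_delta: float = 1.0,
    seed: int = 0,
) -> EffectModel:
    """Fit the nine-parameter robust linear composition model.

    The response is delta-logit(PSI) for exon skipping or the allelic
    log-ratio for splicing efficiency. Fitting minimizes the Huber loss
    (transition at ``huber_delta``) so gross outliers do not dominate;
    the scoring-module weights themselves are never updated here.
    """
    from scipy.optimize import least_squares

    if purpose == "pathogenicity":
        raise ValueError("use fit_pathogenicity for the pathogenicity model")
    y = np.asarray(response, dtype=np.float64)
    X = feature_matrix(rows, "delta")
    n, k = X.shape
    if y.size != n:
        raise ValueError("row/response length mismatch")
    if n < k + 1:
        raise ValueError(f"{n} rows cannot identify {k + 1} parameters")
    variances = X.var(axis=0)
    dead = [FEATURE_NAMES[i] for i in np.flatnonzero(variances == 0)]
    if dead:
        warnings.warn(f"zero-variance design columns: {dead}", stacklevel=2)

    A = np.column_stack([np.ones(n), X])
    beta0, *_ = np.linalg.lstsq(A, y, rcond=None)

    def residual(beta):
        return A @ beta - y

    fit = least_squares(
        residual, beta0, jac=lambda beta: A, loss="huber",
        f_scale=huber_delta, method="trf", max_nfev=2000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return EffectModel(
        purpose=purpose,
        coef=fit.x,
        feature_names=FEATURE_NAMES,
        meta={"n": int(n), "loss": float(fit.cost), "huber_delta": huber_delta},
    )


def predict_delta_psi(
    model: EffectModel,
    scores: ModuleDeltaScores | Sequence[ModuleDeltaScores],
    psi_ref,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (delta_logit_psi, delta_psi) given reference PSI.

    ``psi_ref`` is clipped into [1e-5, 1 - 1e-5] before the logit, so
    boundary values stay finite. delta_psi = sigma(dlogit + logit(psi_ref))
    - psi_ref.
    """
    single = isinstance(scores, ModuleDeltaScores)
    rows = [scores] if single else list(scores)
    dlogit = model.predict(rows)
    pr = clip_psi(np.broadcast_to(np.asarray(psi_ref, dtype=np.float64), dlogit.shape))
    psi_alt = sigmoid(dlogit + logit(pr))
    dpsi = psi_alt - pr
    if single:
        return float(dlogit[0]), float(dpsi[0])
    return dlogit, dpsi


def delta_psi_from_dlogit(dlogit, psi_ref):
    """delta-PSI for a given delta-logit(PSI) and reference PSI."""
    pr = clip_psi(psi_ref)
    return sigmoid(np.asarray(dlogit, dtype=np.float64) + logit(pr)) - pr


def predict_competition(dlogit1, dlogit2, psi5_ref, genotype: str = "hom_alt"):
    """Change in PSI5 for two competing acceptor sites (or PSI3, donors).

    ``dlogit1`` / ``dlogit2`` are the composition-model predictions for
    the two competing exons; their difference is the change of
    logit(PSI5). Heterozygotes express both alleles equally, so their
    effect is exactly half the homozygous one.
    """
    if genotype not in ("hom_alt", "het"):
        raise ValueError("genotype must be 'hom_alt' or 'het'")
    pr = clip_psi(psi5_ref)
    dlogit5 = np.asarray(dlogit1, dtype=np.float64) - np.asarray(dlogit2, dtype=np.float64)
    psi5_alt = sigmoid(dlogit5 + logit(pr))
    hom = psi5_alt - pr
    return hom if genotype == "hom_alt" else hom / 2.0


def allelic_log_ratio(m_o, m_i, w_o, w_i, pseudocount: float = 0.0):
    """log2 allelic ratio of mutant to wild-type spliced/input counts.

    ``m_o``/``m_i`` are mutant spliced and input read counts, ``w_o``/
    ``w_i`` the wild-type ones. Antisymmetric under swapping mutant and
    wild-type.
    """
    counts = [np.asarray(c, dtype=np.float64) + pseudocount for c in (m_o, m_i, w_o, w_i)]
    if any(np.any(c <= 0) for c in counts):
        raise ValueError("zero or negative counts; enable a pseudocount")
    m_o, m_i, w_o, w_i = counts
    out = np.log2((m_o / m_i) / (w_o / w_i))
    return out if out.ndim else float(out)


def fit_pathogenicity(
    rows: Sequence[ModuleDeltaScores],
    labels: np.ndarray,
    feature_set: str = "delta",
    seed: int = 0,
) -> EffectModel:
    """Logistic regression classifying pathogenic versus benign variants.

    Features are the five dS values and three overlap indicators
    ('delta', nine parameters with intercept) or additionally the five
    reference-allele scores ('extended', fourteen parameters). Callers
    restrict variants to splice-region windows and drop stop-gain
    variants beforehand.
    """
    from sklearn.linear_model import LogisticRegression

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = feature_matrix(rows, feature_set)
    clf = LogisticRegression(C=np.inf, max_iter=5000, random_state=seed)
    clf.fit(X, y)
    names = FEATURE_NAMES if feature_set == "delta" else FEATURE_NAMES + REF_SCORE_NAMES
    return EffectModel(
        purpose="pathogenicity",
        coef=np.concatenate([clf.intercept_, clf.coef_.reshape(-1)]),
        feature_names=names,
        meta={"n": int(y.size), "feature_set": feature_set},
    )


def predict_pathogenicity(model: EffectModel, rows: Sequence[ModuleDeltaScores] | np.ndarray) -> np.ndarray:
    """Probability of pathogenicity under a fitted logistic model."""
    if model.purpose != "pathogenicity":
        raise ValueError("model purpose is not pathogenicity")
    return sigmoid(model.predict(rows))


def cross_validate_pathogenicity(
    rows: Sequence[ModuleDeltaScores],
    labels: np.ndarray,
    feature_set: str = "delta",
    n_folds: int = 10,
    seed: int = 0,
) -> dict:
    """k-fold cross-validated auROC of the pathogenicity classifier."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    X = feature_matrix(rows, feature_set)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aurocs = []
    for tr, te in skf.split(X, y):
        model = fit_pathogenicity([rows[i] for i in tr], y[tr], feature_set, seed)
        prob = predict_pathogenicity(model, X[te])
        aurocs.append(roc_auc_score(y[te], prob))
    return {"auroc_mean": float(np.mean(aurocs)), "auroc_sd": float(np.std(aurocs)), "folds": aurocs}


def splice_region_window_predicate(
    windows_acceptor: tuple[int, int] = (-40, 10),
    windows_donor: tuple[int, int] = (-10, 10),
):
    """Predicate selecting variants near a splice site.

    Offsets are relative to the junction in transcript orientation
    (negative = upstream). Returns a function of (variant, exon).
    """

    def predicate(variant, exon) -> bool:
        v0, v1 = variant.start, variant.end
        if exon.strand == "+":
            acc = (exon.start + windows_acceptor[0], exon.start + windows_acceptor[1] + 1)
            don = (exon.end - 1 + windows_donor[0], exon.end + windows_donor[1])
        else:
            acc = (exon.end - windows_acceptor[1] - 1, exon.end - windows_acceptor[0])
            don = (exon.start - windows_donor[1], exon.start + 1 - windows_donor[0])
        return (v0 < acc[1] and v1 > acc[0]) or (v0 < don[1] and v1 > don[0])

    return predicate


def classify_sdv(delta_psi: np.ndarray, threshold: float | None = None):
    """Rank variants as splice-disrupting by |delta-PSI|.

    Returns a DataFrame sorted by direction-free effect magnitude with
    an optional hard call at ``threshold``; suited to precision-recall
    evaluation against assay-defined SDV labels.
    """
    import pandas as pd

    dpsi = np.asarray(delta_psi, dtype=np.float64)
    if not np.all(np.isfinite(dpsi)):
        raise ValueError("non-finite predictions")
    score = np.abs(dpsi)
    order = np.argsort(-score, kind="stable")
    df = pd.DataFrame({
        "index": np.arange(dpsi.size),
        "delta_psi": dpsi,
        "score": score,
    })
    df["rank"] = np.empty(dpsi.size, dtype=int)
    df.loc[order, "rank"] = np.arange(1, dpsi.size + 1)
    if threshold is not None:
        df["call"] = score >= threshold
    return df.sort_values("rank").reset_index(drop=True)
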