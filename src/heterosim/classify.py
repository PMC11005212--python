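"""Eight-profile expression classification for hybrid-parent trios.

Each gene is assigned to one of eight profiles — two additive (P0, P7), four
dominant (P1, P3, P4, P6), two overdominant/transgressive (P2, P5) — or left
unclassified, from four statistical contrasts: hybrid vs maternal, hybrid vs
paternal, maternal vs paternal, and hybrid vs the mid-parent value.  This is
the direct pairwise/mid-parent scheme of Swanson-Wagner-style heterosis
studies; "significant" means BH q <= alpha on the relevant contrast.

Decision tree (first match wins; transgressive before dominance before
additive, so the stronger claim needs both of its defining contrasts):

1. hybrid significantly above both parents            -> P5 transgressive-up
2. hybrid significantly below both parents            -> P2 transgressive-down
3. hybrid ~ maternal, hybrid != paternal              -> maternal dominance
   (P6 when maternal > paternal, else P1)
4. hybrid ~ paternal, hybrid != maternal              -> paternal dominance
   (P3 when paternal < maternal, else P4)
5. parents differ, hybrid ~ mid-parent                -> additive
   (P0 when maternal < paternal, else P7)
6. otherwise unclassified

Swapping the parental labels flips P0<->P7, P1<->P3 and P6<->P4 and leaves
P2, P5 and unclassified fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import (
    DEThresholds,
    bh_adjust,
    de_test,
    normalize,
    size_factors,
    squeeze_variances,
)

__all__ = [
    "PROFILE_CATEGORY",
    "PROFILE_COARSE",
    "ROLE_SWAP",
    "midparent_test",
    "trio_test_set",
    "assign_profiles",
    "classify_trio",
    "profile_summary",
]

PROFILE_CATEGORY = {
    "P0": "additive",
    "P7": "additive",
    "P1": "maternal-dominant",
    "P6": "maternal-dominant",
    "P3": "paternal-dominant",
    "P4": "paternal-dominant",
    "P5": "transgressive-up",
    "P2": "transgressive-down",
    "unclassified": "unclassified",
}

#: coarse class used for ground-truth recovery summaries
PROFILE_COARSE = {
    "P0": "additive",
    "P7": "additive",
    "P1": "dominant",
    "P3": "dominant",
    "P4": "dominant",
    "P6": "dominant",
    "P2": "overdominant",
    "P5": "overdominant",
    "unclassified": "null",
}

#: profile relabelling induced by exchanging the maternal and paternal roles
ROLE_SWAP = {
    "P0": "P7",
    "P7": "P0",
    "P1": "P3",
    "P3": "P1",
    "P6": "P4",
    "P4": "P6",
    "P2": "P2",
    "P5": "P5",
    "unclassified": "unclassified",
}

NON_ADDITIVE_PROFILES = ("P1", "P2", "P3", "P4", "P5", "P6")


def midparent_test(
    hybrid: np.ndarray,
    maternal: np.ndarray,
    paternal: np.ndarray,
    pseudocount: float = 1.0,
    moderate: bool = True,
) -> pd.DataFrame:
    """Test hybrid expression against the mid-parent value, per gene.

    ``hybrid``/``maternal``/``paternal`` are gene x replicate arrays of
    *normalized* counts.  The mid-parent reference is the average of the two
    parental group means; the hybrid replicates (log2 scale) are tested
    against it with a one-sample statistic whose variance is squeezed across
    genes when ``moderate``.  Returns per-gene ``log2_ratio``
    (hybrid over mid-parent), ``p``, and the group means.
    """
    hybrid = np.asarray(hybrid, dtype=float)
    maternal = np.asarray(maternal, dtype=float)
    paternal = np.asarray(paternal, dtype=float)
    n_h, n_m, n_p = hybrid.shape[1], maternal.shape[1], paternal.shape[1]
    if min(n_h, n_m, n_p) < 2:
        raise ValueError("need >= 2 replicates per role")
    mean_m, mean_p = maternal.mean(axis=1), paternal.mean(axis=1)
    hyb_mean = hybrid.mean(axis=1)
    mid = (mean_m + mean_p) / 2.0
    undefined = mid == 0

    ln2_sq = np.log(2.0) ** 2
    groups = ((hybrid, n_h, hyb_mean), (maternal, n_m, mean_m), (paternal, n_p, mean_p))
    # per-group log2-scale replicate variances, optionally squeezed across
    # genes toward an expression-level trend (same moderation as the
    # two-sample engine); converted back to natural scale by delta method
    s2_log, dfs = [], []
    for arr, n, mean in groups:
        y = np.log2(arr + pseudocount)
        s2 = y.var(axis=1, ddof=1)
        if moderate:
            post, d0, _ = squeeze_variances(s2, n - 1, covariate=y.mean(axis=1))
            s2_log.append(post)
            dfs.append(n - 1 + d0 if np.isfinite(d0) else np.inf)
        else:
            s2_log.append(s2)
            dfs.append(n - 1)

    # variance of log2(hybrid mean) and of log2(mid-parent), delta method:
    # Var(log2 xbar) ~ Var(xbar) / ((xbar+pc)^2 ln2^2); group variances on
    # the natural scale are recovered as s2_log * ln2^2 * (mean+pc)^2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_h = s2_log[0] / n_h
        denom = (mid + pseudocount) ** 2
        v_m = s2_log[1] * (mean_m + pseudocount) ** 2 / (4.0 * n_m * denom)
        v_p = s2_log[2] * (mean_p + pseudocount) ** 2 / (4.0 * n_p * denom)
        se = np.sqrt(v_h + v_m + v_p)
        ratio = np.log2((hyb_mean + pseudocount) / (mid + pseudocount))
        # Welch-Satterthwaite over the three variance components
        num = (v_h + v_m + v_p) ** 2
        den = v_h**2 / dfs[0] + v_m**2 / dfs[1] + v_p**2 / dfs[2]
        df_total = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        t = np.where(se > 0, ratio / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), np.clip(df_total, 1.0, 1e12))
    p = np.where((se == 0) & (ratio == 0), 1.0, p)
    p = np.where(undefined, 1.0, p)
    ratio = np.where(undefined, np.nan, ratio)
    return pd.DataFrame(
        {
            "log2_ratio": ratio,
            "p": np.clip(p, 0.0, 1.0),
            "mid_parent": mid,
            "mean_hybrid": hyb_mean,
            "undefined": undefined,
        }
    )


def _role_columns(samples: pd.DataFrame, role: str, condition: str | None) -> list:
    sel = samples["role"] == role
    if condition is not None:
        sel &= samples["condition"] == condition
    cols = samples.loc[sel, "sample_id"].tolist()
    if len(cols) < 2:
        raise ValueError(
            f"need >= 2 replicates for role={role!r}"
            + (f", condition={condition!r}" if condition else "")
        )
    return cols


def trio_test_set(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str | None = "stress",
    thresholds: DEThresholds = DEThresholds(),
    engine: str = "moderated",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """All four per-gene contrasts needed by the profile classifier.

    Returns one row per gene with normalized group means, the mid-parent
    value, and (log2FC, p, q) for hybrid-vs-maternal (``hm``),
    hybrid-vs-paternal (``hp``), maternal-vs-paternal (``mp``) and
    hybrid-vs-mid-parent (``hmid``), plus DEG flags for the two
    hybrid-parent contrasts.  FDR is controlled within each contrast.
    """
    required = {"sample_id", "role", "condition"}
    if not required <= set(samples.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    cols_m = _role_columns(samples, "maternal", condition)
    cols_p = _role_columns(samples, "paternal", condition)
    cols_h = _role_columns(samples, "hybrid", condition)
    used = cols_m + cols_p + cols_h
    sub = counts[used]
    factors = size_factors(sub)

    res_hm = de_test(sub, cols_h, cols_m, factors[used], thresholds, engine, pseudocount)
    res_hp = de_test(sub, cols_h, cols_p, factors[used], thresholds, engine, pseudocount)
    res_mp = de_test(sub, cols_m, cols_p, factors[used], thresholds, engine, pseudocount)

    norm = normalize(sub, factors[used])
    mid = midparent_test(
        norm[cols_h].to_numpy(),
        norm[cols_m].to_numpy(),
        norm[cols_p].to_numpy(),
        pseudocount,
        moderate=(engine == "moderated"),
    )

    out = pd.DataFrame(index=counts.index)
    out["mean_maternal"] = res_hm["mean_b"].to_numpy()
    out["mean_paternal"] = res_hp["mean_b"].to_numpy()
    out["mean_hybrid"] = res_hm["mean_a"].to_numpy()
    out["mid_parent"] = mid["mid_parent"].to_numpy()
    for tag, res in (("hm", res_hm), ("hp", res_hp), ("mp", res_mp)):
        out[f"lfc_{tag}"] = res["log2FC"].to_numpy()
        out[f"p_{tag}"] = res["p"].to_numpy()
        out[f"q_{tag}"] = res["q"].to_numpy()
    out["lfc_hmid"] = mid["log2_ratio"].to_numpy()
    out["p_hmid"] = mid["p"].to_numpy()
    out["q_hmid"] = bh_adjust(mid["p"].to_numpy())
    out["deg_hm"] = res_hm["deg"].to_numpy()
    out["deg_hp"] = res_hp["deg"].to_numpy()
    return out


def assign_profiles(tests: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Apply the decision tree to a trio test set; returns per-gene profiles."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    sig_hm = tests["q_hm"].to_numpy() <= alpha
    sig_hp = tests["q_hp"].to_numpy() <= alpha
    sig_mp = tests["q_mp"].to_numpy() <= alpha
    sig_hmid = tests["q_hmid"].to_numpy() <= alpha
    m = tests["mean_maternal"].to_numpy()
    p = tests["mean_paternal"].to_numpy()
    h = tests["mean_hybrid"].to_numpy()

    above_m, above_p = h > m, h > p
    below_m, below_p = h < m, h < p
    m_lt_p = m < p

    profile = np.full(len(tests), "unclassified", dtype=object)
    assigned = np.zeros(len(tests), dtype=bool)

    def take(mask, labels):
        use = mask & ~assigned
        profile[use] = labels[use] if isinstance(labels, np.ndarray) else labels
        assigned[use] = True

    take(sig_hm & sig_hp & above_m & above_p, "P5")
    take(sig_hm & sig_hp & below_m & below_p, "P2")
    take(~sig_hm & sig_hp, np.where(m_lt_p, "P1", "P6"))
    take(~sig_hp & sig_hm, np.where(p < m, "P3", "P4"))
    take(sig_mp & ~sig_hmid, np.where(m_lt_p, "P0", "P7"))
    return pd.Series(profile, index=tests.index, name="profile")


def classify_trio(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str | None = "stress",
    alpha: float = 0.05,
    universe: str = "deg",
    thresholds: DEThresholds = DEThresholds(),
    engine: str = "moderated",
) -> pd.DataFrame:
    """Classify every gene of a trio experiment into the eight profiles.

    ``universe="deg"`` (default) restricts classification to genes that are
    differentially expressed in at least one hybrid-vs-parent contrast —
    the set trend analysis is run on — leaving the rest unclassified;
    ``universe="all"`` classifies every gene.
    """
    if universe not in ("deg", "all"):
        raise ValueError("universe must be 'deg' or 'all'")
    tests = trio_test_set(counts, samples, condition, thresholds, engine)
    profile = assign_profiles(tests, alpha)
    in_universe = (
        (tests["deg_hm"] | tests["deg_hp"])
        if universe == "deg"
        else pd.Series(True, index=tests.index)
    )
    profile = profile.where(in_universe, "unclassified")
    out = tests.copy()
    out["in_universe"] = in_universe
    out["profile"] = profile
    out["category"] = profile.map(PROFILE_CATEGORY)
    out["coarse"] = profile.map(PROFILE_COARSE)
    return out


def profile_summary(assignments: pd.DataFrame, deg_universe=None) -> dict:
    """Per-profile counts and the non-additive fraction of the DEG universe.

    ``deg_universe`` is the gene set the fraction is computed over (defaults
    to the genes flagged ``in_universe``).  Non-additive genes are those in
    the dominance or transgressive profiles (P1-P6).
    """
    if deg_universe is None:
        if "in_universe" not in assignments.columns:
            raise ValueError("no deg_universe given and no in_universe column")
        deg_universe = set(assignments.index[assignments["in_universe"]])
    else:
        deg_universe = set(deg_universe)
    if not deg_universe:
        raise ValueError("empty DEG universe")
    counts = assignments["profile"].value_counts().to_dict()
    in_uni = assignments.index.isin(deg_universe)
    non_additive = int(
        (assignments["profile"].isin(NON_ADDITIVE_PROFILES) & in_uni).sum()
    )
    return {
        "profile_counts": {k: int(counts.get(k, 0)) for k in PROFILE_CATEGORY},
        "non_additive": non_additive,
        "universe_size": len(deg_universe),
        "non_additive_pct": non_additive / len(deg_universe) * 100.0,
    }
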