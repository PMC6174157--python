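"""Per-pair differential expression by a negative-binomial exact test.

The design is one tumor and one normal library per patient, with no
replicates, so no dispersion can be estimated from the data; a dispersion
must be supplied (default 0.1, a common fallback for no-replicate
human-tissue designs) and is recorded in every result row.

The test conditions on the total of the two (library-equalized) counts:
libraries are first scaled to their geometric mean with half-to-even
rounding, then, conditional on the sum ``s``, each split ``i`` in
``[0, s]`` receives weight ``w(i) = NB(i; mu=s/2, phi) * NB(s-i; mu=s/2,
phi)`` and the two-sided p-value is the normalized mass of all splits at
most as probable as the observed one (with a 1+1e-9 relative tie
tolerance).  As phi -> 0 this reduces to the exact two-tailed
Binomial(s, 1/2) test.

Calling rule: a feature is ``up`` in a pair iff log2 fold change >
log2(fc_threshold) and FDR < fdr_threshold (Benjamini-Hochberg within the
pair); ``down`` symmetrically; otherwise ``ns``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .quantify import CountMatrix, compute_cpm, filter_expressed

_TIE_LOG_TOL = math.log1p(1e-9)
# Full enumeration below this total; windowed evaluation above (see _cond_p).
_ENUM_MAX = 4096
_P_FLOOR = 1e-300

DE_COLUMNS = [
    "feature_id",
    "pair_id",
    "log2_fc",
    "p_value",
    "fdr",
    "direction",
    "dispersion_used",
]


def _nb_logpmf(i: np.ndarray, mu: float, phi: float) -> np.ndarray:
    """Log pmf of NB with mean mu and dispersion phi (var = mu + phi*mu^2)."""
    i = np.asarray(i, dtype=float)
    if phi == 0.0:
        return i * math.log(mu) - mu - gammaln(i + 1.0)
    r = 1.0 / phi
    return (
        gammaln(i + r)
        - gammaln(r)
        - gammaln(i + 1.0)
        + r * math.log(r / (r + mu))
        + i * math.log(mu / (r + mu))
    )


def _cond_p_enum(ya: int, s: int, phi: float) -> float:
    """Two-sided conditional p by full enumeration of all splits."""
    i = np.arange(s + 1)
    mu = s / 2.0
    lw = _nb_logpmf(i, mu, phi) + _nb_logpmf(s - i, mu, phi)
    m = lw.max()
    w = np.exp(lw - m)
    mask = lw <= lw[ya] + _TIE_LOG_TOL
    p = float(w[mask].sum() / w.sum())
    return min(1.0, max(p, _P_FLOOR))


def _cond_p_window(ya: int, s: int, phi: float) -> float:
    """Two-sided conditional p for large totals.

    Exploits the exact symmetry w(i) = w(s - i) and the unimodality of the
    conditional weights (phi < 1): the "as or less probable" set is the two
    tails [0..k] and [s-k..s] with k = min(ya, s - ya).  Sums are truncated
    where terms fall ~1e-22 below the peak; the truncation error is far
    below any thresholding use of the p-value.
    """
    mu = s / 2.0
    k = min(ya, s - ya)
    sd = math.sqrt(mu + phi * mu * mu)
    h = int(10.0 * sd) + 12
    m0 = s // 2
    # total mass around the mode
    i0 = np.arange(max(0, m0 - h), min(s, m0 + h) + 1)
    lw = _nb_logpmf(i0, mu, phi) + _nb_logpmf(s - i0, mu, phi)
    peak = lw.max()
    total = np.exp(lw - peak).sum()
    # one tail, from k downward
    j = np.arange(max(0, k - h), k + 1)
    lwj = _nb_logpmf(j, mu, phi) + _nb_logpmf(s - j, mu, phi)
    tail = np.exp(lwj - peak).sum()
    p = 2.0 * tail
    if 2 * k == s:  # observed split is the mode; tails cover everything
        p -= math.exp(lwj[-1] - peak)
    p /= total
    # guarantee the observed split itself is always counted
    obs = math.exp(lwj[-1] - peak) / total
    return min(1.0, max(p, obs, _P_FLOOR))


def _cond_p(ya: int, s: int, phi: float) -> float:
    if s == 0:
        return 1.0
    if s <= _ENUM_MAX or phi >= 1.0:
        return _cond_p_enum(ya, s, phi)
    return _cond_p_window(ya, s, phi)


def _equalize(count: int, lib: int, lib_star: float) -> int:
    # numpy round is half-to-even
    return int(np.round(count * (lib_star / lib)))


def nb_exact_test(
    count_a: int, count_b: int, lib_a: int, lib_b: int, dispersion: float
) -> float:
    """Exact two-sided NB test of one count against another.

    Counts are first equalized to the geometric mean of the two library
    sizes (half-to-even rounding); the p-value is then computed
    conditionally on the equalized total as described in the module
    docstring.  Returns p in (0, 1].
    """
    if count_a < 0 or count_b < 0:
        raise InputError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise InputError("library sizes must be positive")
    if dispersion < 0:
        raise InputError("dispersion must be non-negative")
    lib_star = math.sqrt(float(lib_a) * float(lib_b))
    ya = _equalize(count_a, lib_a, lib_star)
    yb = _equalize(count_b, lib_b, lib_star)
    return _cond_p(ya, ya + yb, dispersion)


def log2_fold_change(cpm_tumor: float, cpm_normal: float, pseudocount: float = 0.5) -> float:
    """log2((tumor + c) / (normal + c)); antisymmetric under condition swap."""
    if cpm_tumor < 0 or cpm_normal < 0:
        raise InputError("expression values must be non-negative")
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    return math.log2((cpm_tumor + pseudocount) / (cpm_normal + pseudocount))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(log2_fc: float, fdr: float, fc_threshold: float, fdr_threshold: float) -> str:
    if fdr < fdr_threshold:
        if log2_fc > math.log2(fc_threshold):
            return "up"
        if log2_fc < -math.log2(fc_threshold):
            return "down"
    return "ns"


def run_pair_de(
    counts: CountMatrix,
    pair_id: str,
    dispersion: float = 0.1,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    pseudocount: float = 0.5,
    cpm_threshold: float = 1.0,
    cpm_min_samples: int = 1,
    prefilter: bool = True,
) -> pd.DataFrame:
    """Exact-test DE for one tumor/normal pair.

    Features are first restricted to those with CPM above ``cpm_threshold``
    in at least ``cpm_min_samples`` samples of the whole matrix (the
    expression filter); BH adjustment is applied across all retained
    features within the pair.  Returns a DataFrame with columns
    ``feature_id, pair_id, log2_fc, p_value, fdr, direction,
    dispersion_used``.
    """
    tumor, normal = counts.pair_samples(pair_id)
    cpm = compute_cpm(counts)
    if prefilter:
        keep = filter_expressed(cpm, cpm_threshold, cpm_min_samples, mode="gt")
        features = [f for f in counts.feature_ids if f in keep]
    else:
        features = counts.feature_ids
    if not features:
        return pd.DataFrame(columns=DE_COLUMNS)
    lib_t = int(counts.library_sizes[tumor])
    lib_n = int(counts.library_sizes[normal])
    if lib_t <= 0 or lib_n <= 0:
        raise InputError("zero library size in pair")
    lib_star = math.sqrt(float(lib_t) * float(lib_n))
    yt = np.round(counts.counts.loc[features, tumor].to_numpy() * (lib_star / lib_t)).astype(int)
    yn = np.round(counts.counts.loc[features, normal].to_numpy() * (lib_star / lib_n)).astype(int)
    pvals = np.array(
        [_cond_p(int(a), int(a + b), dispersion) for a, b in zip(yt, yn)]
    )
    cpm_t = cpm.values.loc[features, tumor].to_numpy()
    cpm_n = cpm.values.loc[features, normal].to_numpy()
    lfc = np.log2((cpm_t + pseudocount) / (cpm_n + pseudocount))
    fdr = bh_adjust(pvals)
    directions = [
        _direction(f, q, fc_threshold, fdr_threshold) for f, q in zip(lfc, fdr)
    ]
    return pd.DataFrame(
        {
            "feature_id": features,
            "pair_id": pair_id,
            "log2_fc": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": directions,
            "dispersion_used": dispersion,
        }
    )


def run_all_pairs_de(counts: CountMatrix, **kwargs) -> pd.DataFrame:
    """Concatenate :func:`run_pair_de` over every pair in the matrix."""
    tables = [run_pair_de(counts, pair_id, **kwargs) for pair_id in counts.pair_ids]
    return pd.concat(tables, ignore_index=True)


@dataclass
class RecurrenceSummary:
    """Cross-pair direction profile of one feature."""

    feature_id: str
    pairs_up: frozenset
    pairs_down: frozenset
    n_pairs_consistent: int
    coordinated: bool


def summarize_recurrence(
    results: pd.DataFrame | list[pd.DataFrame],
) -> tuple[pd.DataFrame, dict]:
    """Per-feature direction sets and Venn cell counts across pairs.

    ``results`` is one concatenated DE table or a list of per-pair tables.
    A feature is ``coordinated`` when it is called in the same direction in
    every pair present in the input.  The Venn summary maps, for each
    direction, every non-empty pair subset to the number of features called
    in that direction in exactly that subset.

    Returns ``(summary DataFrame, venn dict)``.
    """
    if isinstance(results, list):
        results = pd.concat(results, ignore_index=True)
    if results.duplicated(subset=["feature_id", "pair_id"]).any():
        dup = results[results.duplicated(subset=["feature_id", "pair_id"])]
        raise InputError(
            f"duplicate (feature, pair) rows, e.g. {dup.iloc[0][['feature_id', 'pair_id']].tolist()}"
        )
    all_pairs = frozenset(results["pair_id"])
    n_pairs = len(all_pairs)
    rows = []
    venn: dict[str, dict[frozenset, int]] = {"up": {}, "down": {}}
    for feature_id, grp in results.groupby("feature_id", sort=True):
        up = frozenset(grp.loc[grp["direction"] == "up", "pair_id"])
        down = frozenset(grp.loc[grp["direction"] == "down", "pair_id"])
        n_consistent = max(len(up), len(down))
        coordinated = len(up) == n_pairs or len(down) == n_pairs
        rows.append(
            {
                "feature_id": feature_id,
                "pairs_up": ",".join(sorted(up)),
                "pairs_down": ",".join(sorted(down)),
                "n_pairs_consistent": n_consistent,
                "coordinated": coordinated,
            }
        )
        if up:
            venn["up"][up] = venn["up"].get(up, 0) + 1
        if down:
            venn["down"][down] = venn["down"].get(down, 0) + 1
    summary = pd.DataFrame(
        rows,
        columns=["feature_id", "pairs_up", "pairs_down", "n_pairs_consistent", "coordinated"],
    )
    return summary, venn
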