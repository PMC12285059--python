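"""Concordance audit of two demultiplexing call sets.

Comparing a call set under audit (``test``, e.g. a genotype-based
demultiplexer) against a reference call set (``ref``, e.g. a high-quality
hashing-based run) classifies every droplet called by both into five
categories:

* ``singlet``          — identical sample call in both
* ``partial_stealth``  — a singlet call under audit, multiplet in the
                         reference: a hidden multiplet the audited method
                         failed to flag
* ``multiplet``        — multiplet in both
* ``unassigned``       — unassigned by the method under audit
* ``discordant``       — everything else (sample mismatches, reference
                         unlabelled, ...)

The module also calls double-positive multiplets from per-droplet marker
scores: a two-component Gaussian mixture is fitted per lineage score, the
lower-mean component is taken as the null, and droplets exceeding the null's
upper-tail cut-off in two or more lineages are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .simulate import MULTIPLET_TOKEN, UNASSIGNED_TOKEN, UNLABELLED_TOKEN

__all__ = [
    "RESERVED_TOKENS",
    "ConcordanceResult",
    "classify_concordance",
    "summarise_concordance",
    "two_gaussian_threshold",
    "call_double_positives",
    "partial_stealth_candidates",
]

logger = logging.getLogger(__name__)

RESERVED_TOKENS = (MULTIPLET_TOKEN, UNLABELLED_TOKEN, UNASSIGNED_TOKEN)

CONCORDANCE_CLASSES = (
    "singlet",
    "partial_stealth",
    "multiplet",
    "unassigned",
    "discordant",
)


@dataclass
class ConcordanceResult:
    """Five-way concordance counts over barcodes common to both tables."""

    counts: dict[str, int]
    n_common: int
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    discordant_subtypes: dict[str, int] = field(default_factory=dict)
    n_ref_only: int = 0
    n_test_only: int = 0

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.n_common:
            raise ValueError(f"class counts sum to {total}, expected {self.n_common}")


def _validate_calls(calls: pd.Series, vocabulary: set[str], table: str) -> None:
    allowed = vocabulary | set(RESERVED_TOKENS)
    bad = ~calls.isin(allowed)
    if bad.any():
        row = calls[bad].index[0]
        raise ValueError(
            f"unknown call token {calls[bad].iloc[0]!r} in {table} table at "
            f"barcode {row!r}; declare it in the sample vocabulary or map it "
            f"to a reserved token"
        )


def classify_concordance(
    ref: pd.DataFrame,
    test: pd.DataFrame,
    sample_vocabulary: Optional[Iterable[str]] = None,
) -> ConcordanceResult:
    """Classify each common barcode into the five concordance categories.

    Both inputs are call tables with columns ``barcode`` and ``call``; calls
    are sample names or the reserved tokens MULTIPLET / UNLABELLED /
    UNASSIGNED.  When no vocabulary is declared, the sample names are taken
    to be every non-reserved token seen in either table.
    """
    for name, df in (("ref", ref), ("test", test)):
        if df.empty:
            raise ValueError(f"{name} call table is empty")
        if df["barcode"].duplicated().any():
            dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
            raise ValueError(f"duplicate barcode {dup!r} in {name} table")

    ref_s = ref.set_index("barcode")["call"]
    test_s = test.set_index("barcode")["call"]
    common = ref_s.index.intersection(test_s.index)
    if len(common) == 0:
        raise ValueError("call tables share no barcodes")

    if sample_vocabulary is None:
        vocab = (set(ref_s) | set(test_s)) - set(RESERVED_TOKENS)
    else:
        vocab = set(sample_vocabulary)
    _validate_calls(ref_s, vocab, "ref")
    _validate_calls(test_s, vocab, "test")

    r = ref_s.loc[common].to_numpy(dtype=object)
    t = test_s.loc[common].to_numpy(dtype=object)
    t_is_sample = np.isin(t, list(vocab))

    singlet = t_is_sample & (r == t)
    partial = t_is_sample & (r == MULTIPLET_TOKEN)
    multiplet = (t == MULTIPLET_TOKEN) & (r == MULTIPLET_TOKEN)
    unassigned = t == UNASSIGNED_TOKEN
    discordant = ~(singlet | partial | multiplet | unassigned)

    counts = {
        "singlet": int(singlet.sum()),
        "partial_stealth": int(partial.sum()),
        "multiplet": int(multiplet.sum()),
        "unassigned": int(unassigned.sum()),
        "discordant": int(discordant.sum()),
    }
    per_sample: dict[str, dict[str, int]] = {}
    for sample in sorted(vocab):
        mask = t == sample
        per_sample[sample] = {
            "singlet": int((singlet & mask).sum()),
            "partial_stealth": int((partial & mask).sum()),
        }
    subtypes: dict[str, int] = {}
    for rr, tt in zip(r[discordant], t[discordant]):
        key_r = rr if rr in RESERVED_TOKENS else "sample"
        key_t = tt if tt in RESERVED_TOKENS else "sample"
        key = f"ref={key_r}|test={key_t}"
        subtypes[key] = subtypes.get(key, 0) + 1

    return ConcordanceResult(
        counts=counts,
        n_common=int(len(common)),
        per_sample=per_sample,
        discordant_subtypes=subtypes,
        n_ref_only=int(len(ref_s.index.difference(test_s.index))),
        n_test_only=int(len(test_s.index.difference(ref_s.index))),
    )


def summarise_concordance(res: ConcordanceResult) -> dict:
    """Proportion report: class fractions and stealth-multiplet burden.

    ``partial_stealth_among_monolabelled`` = PS / (singlet + PS) is the
    observable stealth burden; its complement is the singlet-to-monolabelled
    ratio (a lower bound on the TSR — homogeneous stealth multiplets are
    invisible to this audit and still hide among the singlets).
    """
    if res.n_common <= 0:
        raise ValueError("empty concordance result")
    report: dict = {
        "n_common": res.n_common,
        "fractions": {c: res.counts[c] / res.n_common for c in CONCORDANCE_CLASSES},
    }
    mono = res.counts["singlet"] + res.counts["partial_stealth"]
    if mono == 0:
        report["monolabelled_ratios_defined"] = False
    else:
        report["monolabelled_ratios_defined"] = True
        report["partial_stealth_among_monolabelled"] = res.counts["partial_stealth"] / mono
        report["singlet_to_monolabelled_ratio"] = res.counts["singlet"] / mono
    return report


def two_gaussian_threshold(
    scores: Sequence[float],
    p: float = 1e-4,
    adjust: Optional[str] = None,
    max_iter: int = 500,
    random_state: int = 0,
) -> float:
    """Positive/negative cut-off from a two-Gaussian fit of a score vector.

    A two-component Gaussian mixture is fitted by EM (10 restarts, tolerance
    1e-8 on the log-likelihood); the component with the lower mean is the
    null.  The threshold is the smallest score whose null upper-tail
    probability is at most ``p`` — the analytic null quantile
    mu0 + z_{1-p} * sd0 in the default unadjusted mode, or, with
    ``adjust="BY"``, the smallest *observed* score whose
    Benjamini–Yekutieli-adjusted tail probability is at most ``p``.  Scores
    strictly above the threshold are called positive.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 20:
        raise ValueError("need a 1-d vector of at least 20 scores")
    if not (0.0 < p < 0.5):
        raise ValueError("p must lie in (0, 0.5)")
    if adjust not in (None, "BY"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate score distribution: all scores identical")

    gmm = GaussianMixture(
        n_components=2,
        n_init=10,
        tol=1e-8,
        max_iter=max_iter,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm.fit(x.reshape(-1, 1))
    if not gmm.converged_:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations; "
            f"final lower bound {gmm.lower_bound_:.6g}"
        )
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    null = int(np.argmin(means))
    mu0, sd0 = float(means[null]), float(sds[null])
    if not np.isfinite(sd0) or sd0 <= 0:
        raise RuntimeError("degenerate (zero-variance) null component")

    if adjust is None:
        return float(norm.isf(p, loc=mu0, scale=sd0))
    tail = multipletests(norm.sf(x, loc=mu0, scale=sd0), method="fdr_by")[1]
    qualifying = x[tail <= p]
    if qualifying.size == 0:
        raise ValueError(
            f"no score reaches the adjusted null tail probability {p}; "
            f"null fit mean={mu0:.4g} sd={sd0:.4g}"
        )
    return float(qualifying.min())


def call_double_positives(
    score_table: pd.DataFrame,
    thresholds: Mapping[str, float],
    barcode_column: str = "barcode",
) -> list[str]:
    """Barcodes exceeding the lineage threshold in two or more lineages.

    ``score_table`` holds one column per lineage plus a barcode column; rows
    with missing scores in any thresholded lineage are skipped (a warning
    reports how many).
    """
    lineages = list(thresholds)
    missing_cols = [c for c in lineages if c not in score_table.columns]
    if missing_cols:
        raise ValueError(f"score table lacks lineage columns {missing_cols}")
    sub = score_table[[barcode_column, *lineages]]
    complete = sub.dropna(subset=lineages)
    n_skipped = len(sub) - len(complete)
    if n_skipped:
        logger.warning("skipped %d rows with missing scores", n_skipped)
    above = np.column_stack(
        [complete[lin].to_numpy(dtype=float) > thresholds[lin] for lin in lineages]
    )
    mask = above.sum(axis=1) >= 2
    return sorted(complete.loc[mask, barcode_column])


def partial_stealth_candidates(
    double_positives: Iterable[str],
    calls: pd.DataFrame,
    sample_vocabulary: Optional[Iterable[str]] = None,
) -> list[str]:
    """Double-positive barcodes the demultiplexer called monolabelled.

    A droplet scoring positive for two lineages yet carrying a single sample
    call is a partial-stealth multiplet candidate.
    """
    calls_s = calls.set_index("barcode")["call"]
    if sample_vocabulary is None:
        vocab = set(calls_s) - set(RESERVED_TOKENS)
    else:
        vocab = set(sample_vocabulary)
    dp = set(double_positives)
    mono = set(calls_s[calls_s.isin(vocab)].index)
    return sorted(dp & mono)
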