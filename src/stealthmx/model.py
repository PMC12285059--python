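"""Closed-form droplet-class probabilities for sample-multiplexed scRNA-seq.

Droplet occupancy follows a Poisson law with mean ``lam`` cells per droplet.
Each captured cell belongs to sample ``i`` with probability ``r_i`` (pooling
fraction) and carries a detectable sample barcode with probability ``a_i``
(labelling efficiency).  Under this model every droplet falls into exactly one
of seven classes:

========================  =====================================================
empty                     no cell
singlet, labelled         one cell, barcoded
singlet, unlabelled       one cell, no barcode
homogeneous stealth (HS)  >=2 cells, all barcoded, all one sample
partial stealth (PS)      >=2 cells, barcoded cells of one sample + >=1
                          unlabelled cell
multilabelled (Mu)        >=2 cells carrying barcodes of >=2 samples
unlabelled (Un)           >=2 cells, none barcoded
========================  =====================================================

HS and PS droplets are *stealth multiplets*: they look monolabelled and
survive demultiplexing.  The true singlet ratio (TSR) is the fraction of
monolabelled droplets that are genuine singlets.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Convention",
    "ExperimentDesign",
    "MultipletProbabilities",
    "overall_labelling_efficiency",
    "droplet_occupancy_pmf",
    "multiplet_probabilities",
    "equal_design",
    "equal_design_probabilities",
    "true_singlet_ratio",
    "sweep_table",
]

_R_SUM_TOL = 1e-9


class Convention(str, enum.Enum):
    """Normalisation convention for droplet-class probabilities.

    per_droplet      probabilities over all droplets, empty ones included
                     (the canonical storage form; the seven classes sum to 1)
    per_cell_droplet probabilities among droplets containing >=1 cell
                     (divide by 1 - e^{-lam}; what count tables report)
    per_monolabelled probabilities among apparently monolabelled droplets
                     (divide by labelled-singlet + HS + PS mass)
    """

    per_droplet = "per_droplet"
    per_cell_droplet = "per_cell_droplet"
    per_monolabelled = "per_monolabelled"


@dataclass(frozen=True)
class ExperimentDesign:
    """Full parameter set of a multiplexed droplet run.

    Parameters
    ----------
    r
        Pooling fractions, one per sample; must sum to 1.
    a
        Labelling efficiencies, one per sample, each in [0, 1].
    lam
        Poisson mean number of cells per droplet (loading rate); > 0.
    names
        Optional sample names; defaults to ``S1 .. Ss``.
    """

    r: np.ndarray
    a: np.ndarray
    lam: float
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "a", a)
        if r.ndim != 1 or r.size < 1:
            raise ValueError("r must be a non-empty 1-d vector")
        if a.shape != r.shape:
            raise ValueError(f"a has shape {a.shape}, expected {r.shape}")
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("pooling fractions must lie in (0, 1]")
        if abs(r.sum() - 1.0) > _R_SUM_TOL:
            raise ValueError(f"pooling fractions sum to {r.sum():.12g}, expected 1")
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("labelling efficiencies must lie in [0, 1]")
        if not (self.lam > 0):
            raise ValueError("lam must be positive")
        names = tuple(self.names) or tuple(f"S{i + 1}" for i in range(r.size))
        if len(names) != r.size:
            raise ValueError("names length must match sample count")
        object.__setattr__(self, "names", names)

    @property
    def s(self) -> int:
        """Number of multiplexed samples."""
        return int(self.r.size)

    @property
    def abar(self) -> float:
        """Pool-weighted average labelling efficiency."""
        return float(np.dot(self.r, self.a))

    @property
    def unlabelled_fraction(self) -> float:
        """1 - abar, computed as sum r_i (1 - a_i).

        Exact when every a_i is 1 (no cancellation), which keeps the
        partial-stealth and unlabelled-class probabilities at literal zero
        for perfectly labelled designs.
        """
        return float(np.dot(self.r, 1.0 - self.a))


@dataclass(frozen=True)
class MultipletProbabilities:
    """Probabilities of the seven droplet classes under one convention."""

    p_hs: float
    p_ps: float
    p_mu: float
    p_un: float
    p_empty: float
    p_singlet_labelled: float
    p_singlet_unlabelled: float
    convention: Convention = Convention.per_droplet

    def __post_init__(self) -> None:
        object.__setattr__(self, "convention", Convention(self.convention))

    @property
    def multiplet_total(self) -> float:
        """Combined mass of the four multiplet classes."""
        return self.p_hs + self.p_ps + self.p_mu + self.p_un

    def multiplet_fractions(self) -> dict[str, float]:
        """The four classes as fractions among multiplets (sum to 1)."""
        tot = self.multiplet_total
        if tot <= 0:
            raise ValueError("no multiplet mass; fractions undefined")
        return {
            "hs": self.p_hs / tot,
            "ps": self.p_ps / tot,
            "mu": self.p_mu / tot,
            "un": self.p_un / tot,
        }

    def to_convention(self, convention: Convention | str) -> "MultipletProbabilities":
        """Rescale all entries to another normalisation convention."""
        convention = Convention(convention)
        if convention == self.convention:
            return self
        if self.convention != Convention.per_droplet:
            raise ValueError("conversion is only defined from the per_droplet form")
        if convention == Convention.per_cell_droplet:
            denom = 1.0 - self.p_empty
        else:  # per_monolabelled
            denom = self.p_singlet_labelled + self.p_hs + self.p_ps
        if denom <= 0:
            raise ValueError(f"zero mass under convention {convention.value}")
        return replace(
            self,
            p_hs=self.p_hs / denom,
            p_ps=self.p_ps / denom,
            p_mu=self.p_mu / denom,
            p_un=self.p_un / denom,
            p_empty=self.p_empty / denom,
            p_singlet_labelled=self.p_singlet_labelled / denom,
            p_singlet_unlabelled=self.p_singlet_unlabelled / denom,
            convention=convention,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "p_hs": self.p_hs,
            "p_ps": self.p_ps,
            "p_mu": self.p_mu,
            "p_un": self.p_un,
            "p_empty": self.p_empty,
            "p_singlet_labelled": self.p_singlet_labelled,
            "p_singlet_unlabelled": self.p_singlet_unlabelled,
        }


def overall_labelling_efficiency(design: ExperimentDesign) -> float:
    """Pool-weighted average labelling efficiency, abar = sum r_i a_i."""
    return design.abar


def droplet_occupancy_pmf(lam: float, k: int) -> float:
    """Poisson probability of a droplet capturing exactly ``k`` cells."""
    if not (lam > 0):
        raise ValueError("lam must be positive")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a nonnegative integer")
    return float(stats.poisson.pmf(int(k), lam))


def multiplet_probabilities(
    design: ExperimentDesign,
    convention: Convention | str = Convention.per_droplet,
) -> MultipletProbabilities:
    """Closed-form probabilities of all seven droplet classes.

    With S = sum_i e^{r_i a_i lam} the four multiplet classes are

        p_HS = e^{-lam} (S - abar*lam - s)
        p_PS = (e^{-abar*lam} - e^{-lam}) (S - s)
        p_Mu = 1 - e^{-abar*lam} (S - s + 1)
        p_Un = e^{-lam} (e^{(1-abar)lam} - (1-abar)lam - 1)

    and they sum to the overall multiplet mass 1 - e^{-lam} - lam e^{-lam}.
    S - s is evaluated as sum expm1(r_i a_i lam) to avoid cancellation at
    small lam; e^{-abar*lam} - e^{-lam} as e^{-lam} expm1((1-abar)lam).
    """
    lam = design.lam
    abar = design.abar
    unlab = design.unlabelled_fraction
    exp_neg_lam = math.exp(-lam)
    # S - s, computed cancellation-free
    s_minus = float(np.sum(np.expm1(design.r * design.a * lam)))
    em1_unlab = math.expm1(unlab * lam)

    p_hs = exp_neg_lam * (s_minus - abar * lam)
    p_ps = exp_neg_lam * em1_unlab * s_minus
    p_mu = 1.0 - math.exp(-abar * lam) * (s_minus + 1.0)
    p_un = exp_neg_lam * (em1_unlab - unlab * lam)

    probs = MultipletProbabilities(
        p_hs=p_hs,
        p_ps=p_ps,
        p_mu=p_mu,
        p_un=p_un,
        p_empty=exp_neg_lam,
        p_singlet_labelled=lam * exp_neg_lam * abar,
        p_singlet_unlabelled=lam * exp_neg_lam * unlab,
    )
    return probs.to_convention(convention)


def equal_design(s: int, abar: float, lam: float) -> ExperimentDesign:
    """Design with equal pooling and equal labelling (r_i a_i = abar / s)."""
    if s < 1 or int(s) != s:
        raise ValueError("s must be a positive integer")
    if not (0.0 <= abar <= 1.0):
        raise ValueError("abar must lie in [0, 1]")
    s = int(s)
    return ExperimentDesign(r=np.full(s, 1.0 / s), a=np.full(s, float(abar)), lam=lam)


def equal_design_probabilities(s: int, abar: float, lam: float) -> MultipletProbabilities:
    """Simplified equal-design closed forms (r_i a_i = abar/s for every i).

        p_HS = s e^{-lam}(e^{abar*lam/s} - 1) - abar*lam e^{-lam}
        p_PS = s (e^{-abar*lam} - e^{-lam})(e^{abar*lam/s} - 1)
        p_Mu = 1 - e^{-abar*lam}(s(e^{abar*lam/s} - 1) + 1)

    p_Un is unchanged from the general form.  Kept separate from
    :func:`multiplet_probabilities` so the two derivations can be checked
    against each other.
    """
    if s < 1 or int(s) != s:
        raise ValueError("s must be a positive integer")
    if not (lam > 0):
        raise ValueError("lam must be positive")
    s = int(s)
    exp_neg_lam = math.exp(-lam)
    em1_share = math.expm1(abar * lam / s)  # e^{abar*lam/s} - 1
    em1_unlab = math.expm1((1.0 - abar) * lam)
    return MultipletProbabilities(
        p_hs=s * exp_neg_lam * em1_share - abar * lam * exp_neg_lam,
        p_ps=s * exp_neg_lam * em1_unlab * em1_share,
        p_mu=1.0 - math.exp(-abar * lam) * (s * em1_share + 1.0),
        p_un=exp_neg_lam * (em1_unlab - (1.0 - abar) * lam),
        p_empty=exp_neg_lam,
        p_singlet_labelled=lam * exp_neg_lam * abar,
        p_singlet_unlabelled=lam * exp_neg_lam * (1.0 - abar),
    )


def true_singlet_ratio(design: ExperimentDesign) -> float:
    """Fraction of monolabelled droplets that are genuine singlets.

        TSR = abar * lam * e^{-lam(1-abar)} / (sum_i e^{r_i a_i lam} - s)

    equivalently P(1)*abar / (P(1)*abar + p_HS + p_PS).  Undefined when no
    sample is labelled (abar = 0).
    """
    abar = design.abar
    if abar <= 0.0:
        raise ValueError("TSR is undefined when the overall labelling efficiency is 0")
    s_minus = float(np.sum(np.expm1(design.r * design.a * design.lam)))
    return (
        abar
        * design.lam
        * math.exp(-design.lam * design.unlabelled_fraction)
        / s_minus
    )


_SWEEP_AXES = ("labelling_efficiency", "sample_count", "lam")


def sweep_table(
    axis: str,
    grid: Sequence[float] | Iterable[float],
    *,
    s: int = 5,
    abar: float = 0.9,
    lam: float = 0.3,
) -> pd.DataFrame:
    """Class composition and TSR along one swept parameter (equal design).

    Returns one row per grid point with the four multiplet classes expressed
    as fractions *among multiplets* (the area-chart convention), the TSR, and
    the overall per-droplet multiplet probability.  The non-swept parameters
    are held at the given values.
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"axis must be one of {_SWEEP_AXES}, got {axis!r}")
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("empty sweep grid")
    rows = []
    for value in grid:
        s_i, abar_i, lam_i = s, abar, lam
        if axis == "labelling_efficiency":
            abar_i = float(value)
        elif axis == "sample_count":
            s_i = int(value)
        else:
            lam_i = float(value)
        probs = multiplet_probabilities(equal_design(s_i, abar_i, lam_i))
        frac = probs.multiplet_fractions()
        design = equal_design(s_i, abar_i, lam_i)
        tsr = true_singlet_ratio(design) if abar_i > 0 else float("nan")
        rows.append(
            {
                axis: value,
                "frac_hs": frac["hs"],
                "frac_ps": frac["ps"],
                "frac_mu": frac["mu"],
                "frac_un": frac["un"],
                "tsr": tsr,
                "p_multiplet": probs.multiplet_total,
            }
        )
    return pd.DataFrame(rows)
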