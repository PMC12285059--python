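"""Seeded Monte-Carlo droplet simulator.

Brute-force oracle for the closed forms in :mod:`stealthmx.model` and fixture
factory for demultiplexing-concordance experiments.  Droplet contents are
drawn by Poisson thinning: a droplet's cell count k ~ Poisson(lam) with each
cell assigned to sample i with probability r_i and labelled with probability
a_i is distributionally identical to independent Poisson counts per
(sample, labelled?) channel with rates lam*r_i*a_i and lam*r_i*(1-a_i).
Randomness comes from numpy's PCG64 generator seeded explicitly, so a fixed
seed reproduces identical tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import ExperimentDesign

__all__ = [
    "CLASS_LABELS",
    "MULTIPLET_TOKEN",
    "UNLABELLED_TOKEN",
    "UNASSIGNED_TOKEN",
    "DropletComposition",
    "DropletPoolTally",
    "classify_droplet",
    "simulate_pool",
    "degrade_calls",
]

# droplet classes, in the order used throughout the package
CLASS_LABELS = (
    "empty",
    "singlet_labelled",
    "singlet_unlabelled",
    "hs",
    "ps",
    "mu",
    "un",
)

# reserved call-table tokens
MULTIPLET_TOKEN = "MULTIPLET"
UNLABELLED_TOKEN = "UNLABELLED"
UNASSIGNED_TOKEN = "UNASSIGNED"


@dataclass(frozen=True)
class DropletComposition:
    """Contents of one droplet.

    ``labelled_counts[i]`` is the number of cells carrying sample i's barcode;
    ``unlabelled_count`` counts cells with no detectable label regardless of
    their sample of origin (classification cannot see the origin, so it is not
    recorded here).
    """

    labelled_counts: tuple[int, ...]
    unlabelled_count: int

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.labelled_counts)
        object.__setattr__(self, "labelled_counts", counts)
        if any(c < 0 for c in counts) or self.unlabelled_count < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return sum(self.labelled_counts) + self.unlabelled_count


def classify_droplet(comp: DropletComposition) -> str:
    """Assign one of the seven droplet classes.

    With k cells, L distinct labelled samples and U unlabelled cells:
    k=0 -> empty; k=1 -> labelled or unlabelled singlet; k>=2 and L>=2 ->
    multilabelled; L=1, U=0 -> homogeneous stealth; L=1, U>=1 -> partial
    stealth; L=0 -> unlabelled multiplet.

    Note the asymmetry that makes partial stealth its own class: a droplet
    whose labelled cells all come from sample i *plus* an unlabelled cell —
    even one that originated from sample i — is partial stealth, not
    homogeneous stealth.
    """
    k = comp.n_cells
    if k == 0:
        return "empty"
    n_labelled_samples = sum(1 for c in comp.labelled_counts if c > 0)
    if k == 1:
        return "singlet_labelled" if n_labelled_samples == 1 else "singlet_unlabelled"
    if n_labelled_samples >= 2:
        return "mu"
    if n_labelled_samples == 1:
        return "hs" if comp.unlabelled_count == 0 else "ps"
    return "un"


@dataclass
class DropletPoolTally:
    """Class counts (and optional per-droplet records) of a simulated pool."""

    design: ExperimentDesign
    n_droplets: int
    seed: int
    counts: dict[str, int]
    per_sample_singlets: dict[str, int]
    droplets: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.n_droplets:
            raise ValueError(f"class counts sum to {total}, expected {self.n_droplets}")

    @property
    def n_cell_droplets(self) -> int:
        return self.n_droplets - self.counts["empty"]

    def frequencies(self, per_cell_droplet: bool = False) -> dict[str, float]:
        denom = self.n_cell_droplets if per_cell_droplet else self.n_droplets
        classes = CLASS_LABELS[1:] if per_cell_droplet else CLASS_LABELS
        return {c: self.counts[c] / denom for c in classes}


def _classify_arrays(
    labelled: np.ndarray, unlabelled: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised droplet classification.

    Returns (class index into CLASS_LABELS, total cells) per droplet.
    """
    n_lab = labelled.sum(axis=1)
    k = n_lab + unlabelled
    n_samples_hit = (labelled > 0).sum(axis=1)
    cls = np.select(
        [
            k == 0,
            (k == 1) & (n_lab == 1),
            k == 1,
            n_samples_hit >= 2,
            (n_samples_hit == 1) & (unlabelled == 0),
            n_samples_hit == 1,
        ],
        [0, 1, 2, 5, 3, 4],
        default=6,
    )
    return cls, k


def simulate_pool(
    design: ExperimentDesign,
    n_droplets: int,
    seed: int,
    keep_droplets: bool = False,
) -> DropletPoolTally:
    """Simulate ``n_droplets`` droplets and tally the seven classes.

    With ``keep_droplets`` the tally carries a per-droplet DataFrame
    (barcode, n_cells, composition, latent_class, apparent_call) suitable for
    :func:`degrade_calls`.  The apparent call is what a perfect demultiplexer
    would report: stealth multiplets and labelled singlets show a single
    sample name, multilabelled droplets MULTIPLET, label-free droplets
    UNLABELLED.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng(seed)
    s = design.s
    lab_rates = design.lam * design.r * design.a
    unlab_rate = float(design.lam * np.sum(design.r * (1.0 - design.a)))

    labelled = rng.poisson(lab_rates, size=(n_droplets, s))
    unlabelled = rng.poisson(unlab_rate, size=n_droplets)
    cls, k = _classify_arrays(labelled, unlabelled)

    counts = {name: int((cls == i).sum()) for i, name in enumerate(CLASS_LABELS)}
    # which sample a labelled singlet belongs to
    singlet_mask = cls == 1
    singlet_sample = labelled[singlet_mask].argmax(axis=1)
    per_sample = {
        name: int((singlet_sample == i).sum()) for i, name in enumerate(design.names)
    }

    droplets = None
    if keep_droplets:
        latent = np.array(CLASS_LABELS, dtype=object)[cls]
        # single labelled sample for monolabelled droplets (singlet/hs/ps)
        mono_mask = np.isin(cls, (1, 3, 4))
        sample_idx = np.full(n_droplets, -1)
        sample_idx[mono_mask] = labelled[mono_mask].argmax(axis=1)
        names = np.array(design.names, dtype=object)
        apparent = np.empty(n_droplets, dtype=object)
        apparent[mono_mask] = names[sample_idx[mono_mask]]
        apparent[cls == 5] = MULTIPLET_TOKEN
        apparent[np.isin(cls, (2, 6))] = UNLABELLED_TOKEN
        apparent[cls == 0] = ""
        comp = np.array(
            [
                ";".join(
                    [f"{names[j]}={labelled[i, j]}" for j in range(s) if labelled[i, j]]
                    + ([f"unlabelled={unlabelled[i]}"] if unlabelled[i] else [])
                )
                for i in range(n_droplets)
            ],
            dtype=object,
        )
        droplets = pd.DataFrame(
            {
                "barcode": [f"bc{i:08d}" for i in range(n_droplets)],
                "n_cells": k,
                "composition": comp,
                "latent_class": latent,
                "apparent_call": apparent,
            }
        )

    return DropletPoolTally(
        design=design,
        n_droplets=int(n_droplets),
        seed=int(seed),
        counts=counts,
        per_sample_singlets=per_sample,
        droplets=droplets,
    )


def degrade_calls(
    pool: DropletPoolTally,
    p_unassign: float,
    p_misassign: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate an imperfect demultiplexer on a simulated pool.

    Returns ``(truth, degraded)`` call tables over the pool's cell-droplets.
    The truth table holds each droplet's apparent call (stealth multiplets
    appear as their single sample name; the latent class is kept in a side
    column).  The degraded table independently replaces each call with
    UNASSIGNED with probability ``p_unassign`` or with a uniformly chosen
    *different* sample with probability ``p_misassign``.
    """
    if pool.droplets is None:
        raise ValueError("pool was simulated without keep_droplets=True")
    if not (0.0 <= p_unassign <= 1.0 and 0.0 <= p_misassign <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if p_unassign + p_misassign > 1.0:
        raise ValueError("p_unassign + p_misassign must not exceed 1")

    cells = pool.droplets[pool.droplets["latent_class"] != "empty"].reset_index(drop=True)
    truth = cells[["barcode", "apparent_call", "latent_class"]].rename(
        columns={"apparent_call": "call"}
    )

    rng = np.random.default_rng(seed)
    n = len(truth)
    u = rng.random(n)
    calls = truth["call"].to_numpy(dtype=object).copy()
    names = list(pool.design.names)

    unassign = u < p_unassign
    misassign = (~unassign) & (u < p_unassign + p_misassign)
    calls[unassign] = UNASSIGNED_TOKEN
    for i in np.flatnonzero(misassign):
        choices = [nm for nm in names if nm != calls[i]]
        calls[i] = choices[rng.integers(len(choices))] if choices else calls[i]

    degraded = pd.DataFrame({"barcode": truth["barcode"], "call": calls})
    return truth, degraded
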