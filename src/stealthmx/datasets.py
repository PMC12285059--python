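"""Published demultiplexing tallies used as worked examples.

Two public sample-multiplexed datasets with reported per-class droplet counts:

* an 8-donor PBMC CITE-seq cell-hashing run (HTO labels, demultiplexed from
  hashtag counts); per-HTO monolabelled counts plus multiplet and unlabelled
  tallies;
* the 10x Genomics "40k NSCLC DTCs from 7 donors" CellPlex run (CMO labels);
  per-CMO monolabelled counts plus the multiplet tally — no droplet was
  called unlabelled.

These tables are inputs for the worked parameter-recovery examples: the
labelling efficiency follows from the monolabelled/unlabelled split and the
loading rate from the multilabelled fraction.
"""

from __future__ import annotations

from .inference import ObservedCounts

__all__ = [
    "CITESEQ_PBMC_SAMPLES",
    "NSCLC_CMO_SAMPLES",
    "citeseq_pbmc_counts",
    "nsclc_cmo_counts",
    "CITESEQ_CONCORDANCE_COUNTS",
    "NSCLC_CONCORDANCE_COUNTS",
]

# 8-donor PBMC hashing run: droplets per HTO call
CITESEQ_PBMC_SAMPLES: dict[str, int] = {
    "HTO_A": 1918,
    "HTO_B": 2001,
    "HTO_C": 1876,
    "HTO_D": 1726,
    "HTO_E": 1493,
    "HTO_F": 1545,
    "HTO_G": 1833,
    "HTO_H": 1874,
}
_CITESEQ_MULTIPLET = 2578
_CITESEQ_UNLABELLED = 72

# 7-donor NSCLC CellPlex run: droplets per CMO call
NSCLC_CMO_SAMPLES: dict[str, int] = {
    "CMO301": 3208,
    "CMO302": 3844,
    "CMO303": 2243,
    "CMO304": 2108,
    "CMO306": 4840,
    "CMO307": 6220,
    "CMO308": 2342,
}
_NSCLC_MULTIPLET = 7864

# five-way concordance counts (genotype demultiplexing audited against the
# label-based reference): singlet, partial_stealth, multiplet, unassigned,
# discordant
CITESEQ_CONCORDANCE_COUNTS: dict[str, int] = {
    "singlet": 13588,
    "partial_stealth": 624,
    "multiplet": 1759,
    "unassigned": 680,
    "discordant": 265,
}
NSCLC_CONCORDANCE_COUNTS: dict[str, int] = {
    "singlet": 24433,
    "partial_stealth": 4285,
    "multiplet": 3561,
    "unassigned": 88,
    "discordant": 302,
}


def citeseq_pbmc_counts() -> ObservedCounts:
    """Class tallies of the 8-donor PBMC hashing run (16,916 cell-droplets)."""
    return ObservedCounts(
        n_mono_total=0,
        n_mono_per_sample=dict(CITESEQ_PBMC_SAMPLES),
        n_unlabelled=_CITESEQ_UNLABELLED,
        n_multilabelled=_CITESEQ_MULTIPLET,
    )


def nsclc_cmo_counts() -> ObservedCounts:
    """Class tallies of the 7-donor NSCLC CellPlex run (32,669 cell-droplets)."""
    return ObservedCounts(
        n_mono_total=0,
        n_mono_per_sample=dict(NSCLC_CMO_SAMPLES),
        n_unlabelled=0,
        n_multilabelled=_NSCLC_MULTIPLET,
    )
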