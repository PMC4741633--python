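"""Published constants for the CIN signature analyses.

Gene lists and cohort bookkeeping figures for the BR9601 and MA.5
anthracycline trials, used as defaults by the synthetic-cohort generator
and by reporting utilities.  The 70-gene CIN panel itself is proprietary
to the original assay; the 21-gene candidate list (grouped by expression
cluster) and the final four-gene signature are public.
"""

from __future__ import annotations

# The four-gene predictive signature (CIN4).
CIN4_GENES: tuple[str, ...] = ("HDGF", "KIAA0286", "RFC4", "MSH6")

# The 21-gene candidate list, grouped by expression cluster (clusters 1-9).
CANDIDATE_CLUSTERS: dict[int, tuple[str, ...]] = {
    1: ("CDC2",),
    2: ("KIF20A",),
    3: ("HDGF",),
    4: ("MDUFAB1", "CDC3A"),
    5: ("CDC6", "MAD2L1", "NXT1", "TOPK"),
    6: ("FEN1", "CCT5"),
    7: ("DKC1", "ECT2"),
    8: ("KIAA0286", "MCM2", "RFC4", "MSH6"),
    9: ("ch.TOG", "CNAP1", "TOP2A", "RRM1"),
}

CANDIDATE_GENES: tuple[str, ...] = tuple(
    g for genes in CANDIDATE_CLUSTERS.values() for g in genes
)

#: Cluster sizes for clusters 1-9 (sums to the 21-gene candidate list).
CANDIDATE_CLUSTER_SIZES: tuple[int, ...] = tuple(
    len(v) for _, v in sorted(CANDIDATE_CLUSTERS.items())
)

# Analysed / randomized sample counts for the two trials.
TRIAL_COUNTS: dict[str, tuple[int, int]] = {
    "BR9601": (282, 321),
    "MA.5": (421, 440),
}

#: Assay panel composition: endogenous targets + reference (normalising) genes.
N_TARGET_GENES = 70
N_REFERENCE_GENES = 6


def analysed_percentage(analysed: int, randomized: int) -> float:
    """Percentage of randomized patients successfully analysed, to one decimal.

    >>> analysed_percentage(282, 321)
    87.9
    """
    if randomized <= 0 or analysed < 0 or analysed > randomized:
        raise ValueError("require 0 <= analysed <= randomized, randomized > 0")
    return round(100.0 * analysed / randomized, 1)


def assayed_gene_count(n_targets: int = N_TARGET_GENES,
                       n_reference: int = N_REFERENCE_GENES) -> int:
    """Total genes assayed on the codeset (targets plus normalising genes)."""
    return int(n_targets) + int(n_reference)
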