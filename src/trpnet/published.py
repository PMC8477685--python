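"""Published strong-edge lists from the DONALD tryptophan network analysis.

The raw cohort data are not public, but the study's reported strong-edge
lists — covariate-adjusted GGM partial correlations and BN bootstrap
strengths per sex and timepoint — are, and they are sufficient inputs for
the whole consensus layer (temporal intersection, cross-method consensus,
report arithmetic). They double as the package's worked example and as
reference fixtures.

Abbreviated forms used below: KYN = kynurenine, KYNA = kynurenic acid,
3HK = 3-hydroxykynurenine, 3HAA = 3-hydroxyanthranilic acid, XA =
xanthurenic acid, IAA = indole-3-acetic acid.
"""

from __future__ import annotations

from .edges import EdgeSet, Provenance

TRP = "tryptophan"
PIC = "picolinic-acid"
QA = "quinolinic-acid"
KYNA = "kynurenic-acid"
KYN = "kynurenine"
XA = "xanthurenic-acid"
ANT = "anthranilic-acid"
HAA = "3-hydroxyanthranilic-acid"
HK = "3-hydroxykynurenine"
SER = "serotonin"
HIAA = "5-hydroxyindole-3-acetic-acid"
HTP = "5-hydroxytryptophan"
IAM = "indole-3-acetamide"
IAA = "indole-3-acetic-acid"
IPA = "indole-3-propionic-acid"
ICALD = "indole-3-carboxaldehyde"
TRM = "tryptamine"

#: Covariate-adjusted GGM strong edges (|pcor| >= 0.3) with signed weights.
GGM_ADJUSTED_STRONG: dict[tuple[str, str], dict[tuple[str, str], float]] = {
    ("male", "baseline"): {
        (IAM, IAA): 0.57,
        (TRP, KYN): 0.42,
        (KYNA, XA): 0.40,
        (KYN, HAA): 0.36,
        (HAA, TRM): 0.33,
        (PIC, ANT): -0.31,
    },
    ("male", "followup"): {
        (KYNA, XA): 0.45,
        (PIC, HTP): -0.36,
        (IAM, IAA): 0.31,
        (TRP, KYN): 0.31,
    },
    ("female", "baseline"): {
        (KYN, HK): 0.47,
        (KYNA, IAA): 0.41,
        (TRP, SER): 0.37,
        (HK, HAA): 0.34,
    },
    ("female", "followup"): {
        (KYNA, IAA): 0.45,
        (HK, HAA): 0.42,
        (KYN, HK): 0.39,
        (IPA, ICALD): 0.31,
        (XA, HIAA): 0.30,
    },
}

#: Covariate-adjusted baseline BN strong edges (strength >= 0.85).
BN_ADJUSTED_BASELINE_STRENGTH: dict[str, dict[tuple[str, str], float]] = {
    "male": {
        (IAM, IAA): 1.0,
        (TRP, KYN): 1.0,
        (KYNA, XA): 1.0,
        (SER, HIAA): 0.93,
        (KYN, HAA): 0.90,
        (PIC, ANT): 0.88,
    },
    "female": {
        (KYNA, IAA): 1.0,
        (KYN, HK): 1.0,
        (IPA, ICALD): 0.98,
        (TRP, SER): 0.95,
        (IAM, IAA): 0.94,
        (PIC, HTP): 0.93,
        (HAA, TRM): 0.91,
        (HK, HAA): 0.90,
        (KYNA, QA): 0.88,
        (TRP, KYN): 0.85,
        (QA, XA): 0.85,
    },
}

#: Follow-up BN strong sets, reported as presence lists: the baseline edges
#: that persisted plus the newly emerged ones (strengths were not reported).
_BN_FOLLOWUP_DROPPED: dict[str, set[tuple[str, str]]] = {
    "male": {(IAM, IAA), (SER, HIAA), (KYN, HAA), (PIC, ANT)},
    "female": {(TRP, SER), (PIC, HTP), (HAA, TRM), (QA, XA)},
}
_BN_FOLLOWUP_NEW: dict[str, set[tuple[str, str]]] = {
    "male": {(PIC, HTP), (KYNA, SER), (KYN, HK)},
    "female": {(PIC, SER), (KYNA, HIAA), (XA, SER), (XA, HIAA), (ANT, HTP)},
}

#: Unadjusted baseline GGM report counts: nonzero edges and strong edges.
BASELINE_NONZERO_EDGES = {"male": 82, "female": 76}
BASELINE_STRONG_EDGES = {"male": 7, "female": 4}


def ggm_strong_edges(sex: str, timepoint: str) -> EdgeSet:
    """The reported covariate-adjusted GGM strong-edge set for one stratum."""
    weights = GGM_ADJUSTED_STRONG[(sex, timepoint)]
    return EdgeSet.from_pairs(
        weights,
        provenance=Provenance(
            method="ggm", sex=sex, timepoint=timepoint, adjusted=True
        ),
    )


def bn_strong_edges(sex: str, timepoint: str) -> EdgeSet:
    """The reported covariate-adjusted BN strong-edge set for one stratum."""
    prov = Provenance(method="bn", sex=sex, timepoint=timepoint, adjusted=True)
    if timepoint == "baseline":
        return EdgeSet.from_pairs(BN_ADJUSTED_BASELINE_STRENGTH[sex], provenance=prov)
    if timepoint != "followup":
        raise KeyError(timepoint)
    from .edges import canonical

    base = {canonical(*p) for p in BN_ADJUSTED_BASELINE_STRENGTH[sex]}
    dropped = {canonical(*p) for p in _BN_FOLLOWUP_DROPPED[sex]}
    new = {canonical(*p) for p in _BN_FOLLOWUP_NEW[sex]}
    return EdgeSet.from_pairs((base - dropped) | new, provenance=prov)
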