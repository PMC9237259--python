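"""Reference values from the original four-group c-Fos mapping experiment.

These are published summary-level results (not raw data) used as worked
examples and cross-checks: the hub-qualification lists produced by the
degree / betweenness ranking in the MPTP and acupuncture groups, the
feature-importance proportions of the linear behavior-prediction model, and
the strongest printed motor-circuit correlations.
"""

from __future__ import annotations

__all__ = [
    "MPTP_DEGREE_QUALIFIED",
    "MPTP_BETWEENNESS_QUALIFIED",
    "ACU_DEGREE_QUALIFIED",
    "ACU_BETWEENNESS_QUALIFIED",
    "ACU_HUBS",
    "GLM_IMPORTANCE_PROPORTIONS_PCT",
    "STRONGEST_NAIVE_MOTOR_R",
]

#: MPTP-group regions with degree >= 5 in the thresholded whole-brain network.
MPTP_DEGREE_QUALIFIED = frozenset(
    {"AcbC", "CA1", "CA3", "PHA", "VA", "AcbSh", "DMS", "CM", "PFC"}
)

#: MPTP-group regions ranked within the top 10 for betweenness centrality.
MPTP_BETWEENNESS_QUALIFIED = frozenset(
    {"PPTg", "SNr", "VTA", "Cg2", "PVN", "Cg1", "Sm", "S1", "AcbSh", "Sol"}
)

#: Acupuncture-group regions with degree >= 5.
ACU_DEGREE_QUALIFIED = frozenset(
    {"PFC", "PVN", "S1", "PPTg", "CM", "Cg2", "PHA", "LC", "AcbC",
     "M1", "VTA", "Cg1", "VL", "CA3", "SNr", "AHA", "DG", "Sm"}
)

#: Acupuncture-group regions ranked within the top 10 for betweenness.
ACU_BETWEENNESS_QUALIFIED = frozenset(
    {"CA3", "PHA", "VL", "IC", "LC", "M1", "DG", "VTA", "Cg1", "CA2"}
)

#: The eight acupuncture-responsive hub regions (degree AND betweenness).
ACU_HUBS = frozenset({"M1", "DG", "CA3", "Cg1", "PHA", "VL", "VTA", "LC"})

#: Linear-model feature-importance proportions (percent, L1-normalized) for
#: predicting rotarod latency. Keys use this package's feature names: the
#: published table labels the nigral TH feature by the region abbreviation,
#: while the accompanying text calls it the TH level in SN; both map to
#: ``th_sn`` here, and striatal TH optical density maps to ``th_st``.
GLM_IMPORTANCE_PROPORTIONS_PCT = {
    "th_sn": 21.3,
    "th_st": 15.7,
    "M1": 13.5,
    "DG": 12.2,
    "Cg1": 10.8,
}

#: Strongest reported untreated-group motor-circuit correlation (DLS-DMS).
STRONGEST_NAIVE_MOTOR_R = 0.986
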