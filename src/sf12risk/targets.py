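"""Published comparison values used as emulation targets.

These numbers summarize the originating clinical cohort and are used only
(a) as calibration targets for the synthetic generator and (b) to label the
"publication" column of comparison reports.  They are never fed back into
any computation as results.
"""

COHORT_N = 217
PREVALENCE_PCT = 29.03
RISK_COUNT = 63

#: Domain / component means and SDs of the published cohort.
DOMAIN_STATS = {
    "PF": (49.54, 30.80),
    "RP": (48.67, 22.60),
    "BP": (60.48, 27.15),
    "GH": (47.86, 19.92),
    "VT": (50.92, 25.78),
    "SF": (64.19, 26.95),
    "RE": (65.44, 26.39),
    "MH": (64.98, 20.74),
    "PCS": (40.94, 7.86),
    "MCS": (47.87, 10.0),
}

#: Covariate marginal rates of the published cohort.
COVARIATE_RATES = {
    "male": 0.654,
    "heart_failure": 0.272,
    "nyha_high": 0.719,
    "ccs_high": 0.797,
}

#: Percent of total variance explained at four components, per method.
VARIANCE_EXPLAINED_K4 = {
    "PCA": 79.33,
    "KPCA": 80.66,
    "GPCA": 81.73,
    "CCPCA": 82.53,
    "LDA_hybrid": 77.72,
}

#: Published per-component eigenvalues and percent-of-variance entries for
#: the supervised (centroid-class) model.
COMPONENT_EIGENVALUES = (3.73, 2.33, 2.19, 1.44)
COMPONENT_PCT_VARIANCE = (31.55, 27.55, 15.33, 7.43)

#: Best published grid cell: CART at four components.
BEST_GRID_CELL = {"classifier": "CART", "k": 4, "accuracy": 0.819}

#: Example risk-path arithmetic quoted alongside the published tree:
#: a parent node at 37.27% whose favorable branch lowers risk by 4.21
#: percentage points to 33.06%.
TREE_PARENT_RISK_PCT = 37.27
TREE_CHILD_DELTA_PCT = -4.21
TREE_CHILD_RISK_PCT = 33.06
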