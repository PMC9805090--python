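"""Worked-example summary tables from a published whole-blood severity
EWAS in females with relapse-onset multiple sclerosis.

These small tables are *inputs* for worked examples and regression
checks of the region-calling, effect-size and tallying arithmetic: the
22 major DMPs (group methylation difference above 5%), the member
coordinates of the two suggestive DMRs, and the cohort-level
context/direction counts of the full 1472-DMP discovery list. They are
summary statistics only; no individual-level data appears here.
"""

from __future__ import annotations

import pandas as pd

# 22 major DMPs: probe, chromosome, 1-based position, gene (empty = IGR),
# genomic feature, CGI context, group delta beta (severe - mild), FDR
_MAJOR_DMP_ROWS = [
    ("cg10070864", "15", 57664490, "", "IGR", "shelf", 0.090, 0.002),
    ("cg07199764", "1", 5347468, "", "IGR", "opensea", -0.113, 0.004),
    ("cg19192981", "15", 57664704, "", "IGR", "shelf", 0.085, 0.004),
    ("cg07499182", "13", 33825496, "STARD13", "body", "opensea", -0.064, 0.005),
    ("cg25304129", "2", 226125490, "", "IGR", "opensea", 0.050, 0.010),
    ("cg17015133", "1", 155111332, "RAG1AP1", "3'UTR", "shore", -0.052, 0.011),
    ("cg14433904", "8", 78518428, "", "IGR", "opensea", 0.056, 0.015),
    ("cg24833027", "8", 1897969, "ARHGEF10", "body", "shelf", 0.067, 0.019),
    ("cg00401101", "5", 16509323, "FAM134B", "TSS1500", "opensea", 0.060, 0.021),
    ("cg08434374", "11", 44467306, "", "IGR", "opensea", 0.057, 0.022),
    ("cg03453431", "7", 157225567, "", "IGR", "opensea", -0.054, 0.023),
    ("cg16958467", "15", 57655799, "", "IGR", "opensea", 0.108, 0.024),
    ("cg00541777", "2", 3652840, "COLEC11", "TSS1500", "opensea", 0.073, 0.033),
    ("cg01156747", "7", 120659, "", "IGR", "island", -0.142, 0.035),
    ("cg17322118", "1", 85743732, "BCL10", "TSS200", "shore", 0.053, 0.035),
    ("cg12257246", "8", 25240570, "DOCK5", "body", "opensea", -0.050, 0.038),
    ("cg00267320", "10", 111533258, "", "IGR", "opensea", 0.058, 0.040),
    ("cg00570954", "12", 94281309, "", "IGR", "opensea", 0.056, 0.042),
    ("cg13883027", "2", 62892060, "", "IGR", "opensea", 0.145, 0.043),
    ("cg25261547", "19", 49363369, "PLEKHA4", "body", "opensea", -0.052, 0.046),
    ("cg21728101", "7", 1979360, "MAD1L1", "body", "shore", -0.052, 0.048),
    ("cg14859874", "1", 154238265, "UBAP2L", "body", "opensea", -0.122, 0.049),
]


def major_dmp_table() -> pd.DataFrame:
    """The published major-DMP summary table, indexed by probe id."""
    return pd.DataFrame(
        _MAJOR_DMP_ROWS,
        columns=[
            "probe_id", "chromosome", "position", "gene",
            "feature", "cgi_context", "delta_meth", "fdr",
        ],
    ).set_index("probe_id")


# Member CpGs of the two suggestive DMRs. The chr11 members are below the
# 5% effect bound so only the stronger one's FDR (0.0087) is published;
# the partner is recorded with a synthetic sub-0.01 placeholder (0.0090),
# which region calling needs only qualitatively (both pass FDR < 0.01).
_DMR_MEMBER_ROWS = [
    ("cg10357314", "11", 94886261, -0.018, 0.0090),
    ("cg02877698", "11", 94886708, -0.018, 0.0087),
    ("cg10070864", "15", 57664490, 0.090, 0.0032),
    ("cg19192981", "15", 57664704, 0.085, 0.0040),
]


def dmr_member_table() -> pd.DataFrame:
    """Member-CpG coordinates and statistics of the two reported DMRs."""
    return pd.DataFrame(
        _DMR_MEMBER_ROWS,
        columns=["probe_id", "chromosome", "position", "delta_meth", "fdr"],
    ).set_index("probe_id")


#: CGI-context counts over the full 1472-CpG discovery DMP list
DISCOVERY_CONTEXT_COUNTS = {"opensea": 1039, "shore": 264, "shelf": 105, "island": 64}

#: direction split of the discovery list (relative to the severe group)
DISCOVERY_DIRECTION_COUNTS = {"hypo": 839, "hyper": 633}

#: discovery cohort size (mild, severe)
COHORT_SIZES = (119, 116)


def discovery_tally_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand the published counts into a per-probe table + annotation.

    Builds a 1472-row stand-in DMP list whose CGI contexts and effect
    directions reproduce the published tallies (the pairing of context
    with direction is arbitrary — only the margins are published), so the
    tallying code path can be exercised on the real totals.
    """
    contexts = [
        c for c, k in DISCOVERY_CONTEXT_COUNTS.items() for _ in range(k)
    ]
    n = len(contexts)
    deltas = [-0.02] * DISCOVERY_DIRECTION_COUNTS["hypo"] + [
        0.02
    ] * DISCOVERY_DIRECTION_COUNTS["hyper"]
    probe_ids = [f"cg_disc{i:05d}" for i in range(n)]
    dmps = pd.DataFrame(
        {"delta_meth": deltas, "p_value": 0.001, "fdr": 0.01},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": "1",
            "position": range(1000, 1000 + n),
            "gene": "",
            "feature": "IGR",
            "cgi_context": contexts,
            "non_cpg": False,
            "snp_related": False,
            "multi_hit": False,
            "autosomal": True,
        }
    )
    return dmps, annotation
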