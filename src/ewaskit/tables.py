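"""Published gene-level DMR tables as typed fixtures.

The discovery-cohort table (24 CpGs, 450K array, 23 MS / 16 control) and
the validation-cohort table (17 CpGs, EPIC array, 12 MS / 12 control)
ship as :class:`~ewaskit.dmp.DMPRecord` lists so the grouping,
replication and span arithmetic can be exercised on real printed rows
without any download.

Rows whose source prints the coordinate in truncated scientific
notation (e.g. ``2.4E+08``) carry ``pos_ambiguous=True`` and must not be
used for span arithmetic; their stored position is the printed value
expanded literally.
"""

from __future__ import annotations

from ewaskit.dmp import DMPRecord

# probe, chrom, pos, mean_control, mean_case, delta, p, gene, feature, cgi
_DISCOVERY_ROWS = [
    ("cg02267270", "6", 37616410, 0.42, 0.53, 0.11, 0.01, "MDGA1", "Body", "Island"),
    ("cg14926196", "6", 37616482, 0.33, 0.51, 0.18, 0.00, "MDGA1", "Body", "Island"),
    ("cg20053110", "6", 37617864, 0.53, 0.64, 0.11, 0.04, "MDGA1", "Body", "Island"),
    ("cg24796644", "6", 37617956, 0.57, 0.70, 0.13, 0.01, "MDGA1", "Body", "Island"),
    ("cg23299919", "7", 157406096, 0.19, 0.30, 0.11, 0.01, "PTPRN2", "Body", "Island"),
    ("cg06715136", "7", 158046025, 0.73, 0.83, 0.11, 0.02, "PTPRN2", "Body", "OpenSea"),
    ("cg09756125", "7", 158250978, 0.66, 0.53, -0.14, 0.02, "PTPRN2", "Body", "Shore"),
    ("cg18200810", "13", 47472200, 0.60, 0.48, -0.11, 0.02, "HTR2A", "TSS1500", "OpenSea"),
    ("cg24118521", "13", 47472330, 0.74, 0.58, -0.16, 0.02, "HTR2A", "TSS1500", "OpenSea"),
    ("cg23881368", "13", 47472343, 0.68, 0.55, -0.13, 0.01, "HTR2A", "TSS1500", "OpenSea"),
    ("cg07075026", "17", 47091521, 0.48, 0.38, -0.10, 0.01, "IGF2BP1", "Body", "Island"),
    ("cg10950924", "17", 47092072, 0.56, 0.46, -0.10, 0.00, "IGF2BP1", "Body", "Island"),
    ("cg18128536", "17", 47092178, 0.59, 0.48, -0.11, 0.00, "IGF2BP1", "Body", "Island"),
    ("cg12099423", "20", 61590751, 0.26, 0.36, 0.11, 0.00, "SLC17A9", "Body", "Shore"),
    ("cg17221813", "20", 61590823, 0.38, 0.51, 0.13, 0.00, "SLC17A9", "Body", "Island"),
    ("cg19142181", "20", 61591066, 0.37, 0.54, 0.17, 0.00, "SLC17A9", "Body", "Island"),
    ("cg07673080", "2", 240241154, 0.89, 0.76, -0.12, 0.00, "HDAC4", "Body", "OpenSea"),
    ("cg10639368", "2", 240241218, 0.80, 0.70, -0.11, 0.00, "HDAC4", "Body", "OpenSea"),
    ("cg18850127", "7", 39170497, 0.65, 0.51, -0.14, 0.01, "POU6F2", "Body", "OpenSea"),
    ("cg20302533", "7", 39170763, 0.56, 0.42, -0.14, 0.00, "POU6F2", "Body", "OpenSea"),
    ("cg06238316", "19", 21265364, 0.22, 0.37, 0.15, 0.00, "ZNF714", "5'UTR", "Island"),
    ("cg09352518", "19", 21265421, 0.24, 0.44, 0.20, 0.00, "ZNF714", "5'UTR", "Island"),
    ("cg17099656", "22", 47135171, 0.17, 0.30, 0.13, 0.00, "CERK", "TSS1500", "OpenSea"),
    ("cg16154810", "22", 47135258, 0.35, 0.55, 0.20, 0.00, "CERK", "TSS1500", "OpenSea"),
]

# last element flags a coordinate printed only in truncated scientific notation
_VALIDATION_ROWS = [
    ("cg06020661", "13", 47472138, 0.75, 0.65, -0.10, 0.01, "HTR2A", "TSS1500", "OpenSea", False),
    ("cg18200810", "13", 47472200, 0.60, 0.47, -0.14, 0.03, "HTR2A", "TSS1500", "OpenSea", False),
    ("cg24118521", "13", 47472330, 0.74, 0.57, -0.17, 0.03, "HTR2A", "TSS1500", "OpenSea", False),
    ("cg23881368", "13", 47472343, 0.69, 0.54, -0.15, 0.02, "HTR2A", "TSS1500", "OpenSea", False),
    ("cg05506829", "13", 47472349, 0.80, 0.69, -0.11, 0.02, "HTR2A", "TSS1500", "OpenSea", False),
    ("cg26371957", "12", 739280, 0.67, 0.80, 0.13, 0.03, "NINJ2", "Body", "OpenSea", False),
    ("cg14911689", "12", 739980, 0.28, 0.50, 0.22, 0.02, "NINJ2", "Body", "OpenSea", False),
    ("cg26654770", "12", 740100, 0.28, 0.55, 0.27, 0.02, "NINJ2", "Body", "OpenSea", False),
    ("cg01201512", "12", 740338, 0.37, 0.60, 0.23, 0.04, "NINJ2", "Body", "OpenSea", False),
    ("cg07673080", "2", 240000000, 0.88, 0.76, -0.11, 0.01, "HDAC4", "Body", "OpenSea", True),
    ("cg10639368", "2", 240000000, 0.80, 0.69, -0.10, 0.02, "HDAC4", "Body", "OpenSea", True),
    ("cg11938672", "6", 170000000, 0.71, 0.59, -0.13, 0.01, "WDR27", "Body", "OpenSea", True),
    ("cg18322025", "6", 170000000, 0.63, 0.47, -0.16, 0.01, "WDR27", "Body", "Shelf", True),
    ("cg18020065", "13", 115000000, 0.34, 0.47, 0.13, 0.01, "RASA3", "Body", "OpenSea", True),
    ("cg16820615", "13", 115000000, 0.73, 0.62, -0.11, 0.00, "RASA3", "Body", "OpenSea", True),
    ("cg17221813", "20", 61590823, 0.39, 0.50, 0.11, 0.03, "SLC17A9", "Body", "Island", False),
    ("cg19142181", "20", 61591066, 0.39, 0.54, 0.15, 0.05, "SLC17A9", "Body", "Island", False),
]


def _make(row) -> DMPRecord:
    ambiguous = row[10] if len(row) > 10 else False
    return DMPRecord(
        probe_id=row[0],
        chrom=row[1],
        pos=row[2],
        mean_control=row[3],
        mean_case=row[4],
        delta_beta=row[5],
        p_value=row[6],
        gene=row[7],
        feature=row[8],
        cgi_relation=row[9],
        pos_ambiguous=ambiguous,
    )


def discovery_dmr_cpgs() -> list[DMPRecord]:
    """The 24 printed discovery-cohort DMR member CpGs."""
    return [_make(r) for r in _DISCOVERY_ROWS]


def validation_dmr_cpgs() -> list[DMPRecord]:
    """The 17 printed validation-cohort DMR member CpGs."""
    return [_make(r) for r in _VALIDATION_ROWS]


def table_fixtures() -> dict[str, list[DMPRecord]]:
    """Both published CpG tables keyed by cohort."""
    return {
        "discovery": discovery_dmr_cpgs(),
        "validation": validation_dmr_cpgs(),
    }
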