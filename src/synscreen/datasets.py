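"""Published reference tables from the seu-3 ant-1 gynoecium screen.

These small curated tables transcribe the published candidate-gene list and
qRT-PCR verification results for the Arabidopsis thaliana *seuss-3
aintegumenta-1* double-mutant gynoecium study (ATH1 arrays, floral stages
8-10; deposited as GEO GSE30492 / ArrayExpress E-MEXP-3293).  They serve as
fixed acceptance surfaces for the synergy and post-hoc machinery — the raw
arrays are deliberately not required.
"""

from __future__ import annotations

import pandas as pd

# AGI, gene title, transcriptional regulator (GO), B3 family, REM subfamily,
# log2 LSmeans for wt / ant / seu / seu ant, -log10 p of the non-additivity
# estimate.
_CANDIDATES = [
    ("At2g46870", "NGATHA1 - B3 domain", True, True, False, 8.42, 8.52, 7.85, 7.17, 5.06),
    ("At3g17010", "REM22 - B3 domain", True, True, True, 10.03, 9.80, 8.60, 7.37, 2.98),
    ("At3g53310", "REM16 - B3 domain", True, True, True, 11.09, 11.00, 10.50, 9.93, 1.58),
    ("At5g18000", "REM20, VERDANDI - B3 domain", True, True, True, 8.55, 7.72, 8.54, 7.02, 3.51),
    ("At5g57720", "REM15 - B3 domain", True, True, True, 9.45, 9.48, 8.97, 8.45, 2.01),
    ("At3g19184", "REM1 - B3 domain", True, True, True, 8.59, 7.77, 8.37, 7.08, 1.65),
    ("At4g31610", "REM34 - B3 domain", True, True, True, 10.18, 10.12, 9.53, 8.98, 1.12),
    ("At4g24150", "AtGRF8, transcriptional regulator", True, False, False, 9.56, 9.03, 9.35, 8.24, 1.78),
    ("At1g31310", "myb-like domain", True, False, False, 9.64, 9.71, 9.22, 8.86, 1.84),
    ("At1g51950", "IAA18, transcription factor", True, False, False, 9.56, 9.18, 9.37, 8.33, 4.17),
    ("At1g68640", "PERIANTHIA, DNA binding", True, False, False, 9.82, 9.04, 9.31, 8.09, 1.22),
    ("At2g34710", "PHABULOSA, transcription factor", True, False, False, 9.49, 9.21, 8.95, 8.24, 2.90),
    ("At3g13960", "AtGRF5, transcriptional regulator", True, False, False, 9.21, 9.30, 8.25, 7.84, 1.61),
    ("At3g55560", "AGF2, DNA-binding protein", True, False, False, 8.47, 8.00, 8.22, 7.26, 2.18),
    ("At4g00180", "YABBY3, transcription factor", True, False, False, 9.27, 8.38, 8.64, 7.05, 2.50),
    ("At4g37750", "AINTEGUMENTA, DNA binding", True, False, False, 10.80, 9.65, 10.69, 8.91, 2.18),
    ("At5g61850", "LEAFY, transcription factor", True, False, False, 9.76, 8.96, 8.90, 7.41, 1.58),
    ("At1g02800", "ATCEL2, cellulase hydrolase", False, False, False, 11.93, 11.47, 11.18, 9.95, 1.90),
    ("At1g68780", "leucine-rich repeat family protein", False, False, False, 8.41, 8.26, 7.74, 6.87, 5.94),
    ("At2g27880", "AGO5, argonaute protein", False, False, False, 10.19, 9.65, 9.98, 8.94, 2.01),
    ("At3g21560", "UGT84A2, UDP-glycosyltransferase", False, False, False, 9.73, 9.71, 8.87, 8.37, 1.38),
    ("At1g01110", "IQD18, calmodulin binding", False, False, False, 8.85, 8.78, 8.30, 7.63, 4.87),
    ("At1g03710", "cystatin-related", False, False, False, 10.19, 10.16, 9.78, 8.81, 4.06),
    ("At1g03720", "cathepsin-related", False, False, False, 9.00, 8.16, 8.41, 7.05, 2.34),
    ("At1g70560", "TAA1 - auxin synthesis", False, False, False, 9.61, 9.07, 9.07, 7.62, 4.90),
    ("At1g73590", "PIN1, auxin transporter", False, False, False, 10.42, 9.99, 10.04, 8.70, 4.02),
    ("At2g21050", "LAX2 - auxin influx carrier", False, False, False, 9.95, 9.57, 10.23, 8.76, 6.11),
    ("At4g25240", "SKS1 (SKU5 SIMILAR 1)", False, False, False, 9.77, 10.09, 9.16, 8.75, 3.63),
    ("At5g07280", "EXCESS MICROSPOROCYTES1 kinase", False, False, False, 10.47, 10.54, 10.03, 9.42, 4.56),
    ("At5g17080", "cathepsin-related", False, False, False, 9.42, 8.56, 9.53, 6.81, 6.34),
    ("At5g48900", "pectate lyase family protein", False, False, False, 8.68, 8.39, 8.22, 7.50, 2.01),
]

#: Size of the Arabidopsis B3 transcription-factor superfamily.
B3_FAMILY_SIZE = 118

#: ATH1 probe sets analysed (the over-representation universe).
ATH1_UNIVERSE_SIZE = 22810


def candidate_genes() -> pd.DataFrame:
    """The 31-gene synergy candidate list with per-genotype log2 LSmeans.

    Columns: ``title``, ``transcriptional_regulator``, ``b3_family``,
    ``rem_subfamily``, ``lsmean_wt``, ``lsmean_ant``, ``lsmean_seu``,
    ``lsmean_double`` and ``neg_log10_p`` (the -log10 p of the published
    non-additivity estimate); indexed by AGI identifier.
    """
    df = pd.DataFrame(
        _CANDIDATES,
        columns=[
            "gene_id",
            "title",
            "transcriptional_regulator",
            "b3_family",
            "rem_subfamily",
            "lsmean_wt",
            "lsmean_ant",
            "lsmean_seu",
            "lsmean_double",
            "neg_log10_p",
        ],
    ).set_index("gene_id")
    return df


# qRT-PCR verification tables: mean normalized expression (relative to the
# APT1 reference, At1g27450), SEM over four biological replicates, and the
# published Tukey-Kramer letter, per genotype.  One assayed candidate
# (At1g31310) was not detected by qPCR and is omitted.
_QPCR_UNDER = [
    ("At4g31610", "REM34", 0.43, 0.03, "A", 0.25, 0.04, "B", 0.33, 0.01, "AB", 0.12, 0.02, "C"),
    ("At2g46870", "NGA1", 0.11, 0.01, "A", 0.04, 0.003, "C", 0.09, 0.004, "B", 0.01, 0.001, "D"),
    ("At1g68640", "PAN", 0.16, 0.02, "A", 0.08, 0.003, "B", 0.06, 0.005, "BC", 0.02, 0.005, "C"),
    ("At3g61970", "NGA2", 0.03, 0.002, "A", 0.01, 0.003, "C", 0.02, 0.002, "B", 0.001, 0.0002, "C"),
    ("At3g55560", "AGF2", 0.07, 0.01, "A", 0.05, 0.005, "B", 0.03, 0.004, "BC", 0.01, 0.002, "C"),
    ("At3g53310", "REM16", 15.78, 0.91, "A", 7.35, 0.41, "C", 12.25, 0.60, "B", 4.15, 0.67, "D"),
    ("At3g21560", "UGT84A2", 0.55, 0.03, "A", 0.22, 0.04, "B", 0.41, 0.04, "A", 0.11, 0.02, "B"),
    ("At5g18000", "VDD", 0.12, 0.01, "A", 0.12, 0.02, "A", 0.04, 0.01, "B", 0.01, 0.001, "B"),
    ("At1g68780", "LRR type", 0.11, 0.01, "A", 0.04, 0.00, "C", 0.07, 0.01, "B", 0.01, 0.001, "D"),
]

_QPCR_OVER = [
    ("At1g20450", "ERD10", 0.03, 0.01, "C", 0.09, 0.03, "B", 0.03, 0.002, "C", 0.16, 0.02, "A"),
    ("At2g15970", "COR413", 0.05, 0.01, "C", 0.16, 0.02, "B", 0.03, 0.01, "C", 0.30, 0.04, "A"),
    ("At1g26960", "ATHB23", 0.03, 0.004, "C", 0.06, 0.004, "B", 0.03, 0.001, "C", 0.11, 0.01, "A"),
    ("At2g33380", "RD20", 0.04, 0.01, "BC", 0.08, 0.005, "B", 0.02, 0.003, "C", 0.15, 0.03, "A"),
    ("At1g05850", "POM1", 0.40, 0.04, "B", 0.42, 0.01, "B", 0.35, 0.03, "B", 0.66, 0.07, "A"),
    ("At1g69780", "ATHB13", 0.23, 0.04, "BC", 0.19, 0.02, "C", 0.29, 0.02, "B", 0.45, 0.02, "A"),
    ("At3g11090", "LBD21", 0.03, 0.004, "B", 0.04, 0.003, "B", 0.02, 0.003, "B", 0.08, 0.01, "A"),
    ("At4g18960", "AG", 19.23, 2.36, "A", 20.21, 2.01, "A", 15.82, 1.06, "A", 22.94, 3.23, "A"),
]

_QPCR_GENOTYPES = ("wild_type", "seu", "ant", "seu_ant")


def _qpcr_frame(rows: list[tuple]) -> pd.DataFrame:
    records = []
    for row in rows:
        gene, name = row[0], row[1]
        for i, genotype in enumerate(_QPCR_GENOTYPES):
            mean, sem, letter = row[2 + 3 * i : 5 + 3 * i]
            records.append((gene, name, genotype, mean, sem, letter))
    return pd.DataFrame(
        records, columns=["gene_id", "name", "genotype", "mean", "sem", "letter"]
    )


def qpcr_verification(direction: str = "under") -> pd.DataFrame:
    """Published qPCR verification table, long format.

    Parameters
    ----------
    direction
        ``"under"`` for candidates with reduced expression in the double
        mutant, ``"over"`` for the elevated set (which includes the AG
        no-change control).
    """
    if direction == "under":
        return _qpcr_frame(_QPCR_UNDER)
    if direction == "over":
        return _qpcr_frame(_QPCR_OVER)
    raise ValueError("direction must be 'under' or 'over'")
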