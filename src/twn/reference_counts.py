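"""Reference 3-ring TWN count tables for arithmetic validation.

Two published surveys of 3-ring TWN frequencies around amino acids
serve as reference data: an MD survey (capped single amino acids in
TIP3P water, energy criterion) and a crystal-structure survey
(high-resolution PDB corpus, O-O distance criterion).  Each survey
reports, per residue type, the number of rings assigned to O, N, C
and S atoms, split into combined / backbone / side-chain scopes,
together with printed Total and ratio rows.

The per-class counts are the raw data; the printed Total and ratio
rows are redundant and must be reproducible from them by the
package's own table arithmetic (Total = O+N+C+S; ratios rounded
half-up to two decimals).  :func:`printed_vs_recomputed` performs
that cross-check and is used by the validation suite and the
acceptance script.

Column order follows the Kyte-Doolittle hydropathy scale (most
hydrophobic first).  ``None`` marks a printed blank.
"""

from __future__ import annotations

from .tables import CountsTable

# fmt: off
MD_RESIDUES = (
    "Ile", "Val", "Leu", "Phe", "Cys", "Met", "Ala", "Gly", "Thr", "Trp",
    "Ser", "Tyr", "Pro", "Hsd", "Hse", "Gln", "Asp", "Asn", "Glu", "Lys", "Arg",
)
PDB_RESIDUES = (
    "Ile", "Val", "Leu", "Phe", "Cys", "Met", "Ala", "Gly", "Thr", "Trp",
    "Ser", "Tyr", "Pro", "His", "Gln", "Asp", "Asn", "Glu", "Lys", "Arg",
)

# Each table: rows O, N, C, S (class counts), then the printed rows
# Total, O,N/Total, C/Total, S/Total.  Blanks are None / 0 counts.
MD_3RING = {
    "combined": {
        "O": (86, 93, 90, 84, 97, 104, 130, 103, 135, 96, 170, 128, 86, 80, 99, 125, 196, 139, 156, 113, 99),
        "N": (25, 28, 37, 15, 13, 37, 28, 65, 20, 38, 21, 23, 33, 80, 70, 73, 19, 60, 27, 51, 81),
        "C": (230, 248, 219, 232, 141, 175, 200, 168, 154, 207, 152, 201, 221, 169, 164, 124, 129, 105, 117, 183, 158),
        "S": (0, 0, 0, 0, 93, 28, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
        "Total": (341, 369, 346, 331, 344, 344, 358, 336, 309, 341, 343, 352, 340, 329, 333, 322, 344, 304, 300, 347, 338),
        "O,N/Total": (0.33, 0.33, 0.37, 0.30, 0.32, 0.41, 0.44, 0.50, 0.50, 0.39, 0.56, 0.43, 0.35, 0.49, 0.51, 0.61, 0.63, 0.65, 0.61, 0.47, 0.53),
        "C/Total": (0.67, 0.67, 0.63, 0.70, 0.41, 0.51, 0.56, 0.50, 0.50, 0.61, 0.44, 0.57, 0.65, 0.51, 0.49, 0.39, 0.37, 0.35, 0.39, 0.52, 0.47),
        "S/Total": (None, None, None, None, 0.27, 0.08, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None),
    },
    "backbone": {
        "O": (86, 93, 90, 84, 97, 104, 130, 103, 91, 96, 95, 109, 86, 80, 99, 87, 88, 97, 79, 113, 99),
        "N": (25, 28, 37, 15, 13, 37, 28, 65, 20, 18, 21, 23, 33, 24, 27, 20, 19, 22, 27, 28, 24),
        "C": (111, 115, 105, 111, 118, 104, 125, 168, 106, 112, 123, 111, 91, 105, 97, 106, 106, 89, 104, 119, 122),
        "S": (0,) * 21,
        "Total": (222, 236, 232, 210, 228, 245, 283, 336, 217, 226, 239, 243, 210, 209, 223, 213, 213, 208, 210, 260, 245),
        "O,N/Total": (0.50, 0.51, 0.55, 0.47, 0.48, 0.58, 0.56, 0.50, 0.51, 0.50, 0.49, 0.54, 0.57, 0.50, 0.57, 0.50, 0.50, 0.57, 0.50, 0.54, 0.50),
        "C/Total": (0.50, 0.49, 0.45, 0.53, 0.52, 0.42, 0.44, 0.50, 0.49, 0.50, 0.51, 0.46, 0.43, 0.50, 0.43, 0.50, 0.50, 0.43, 0.50, 0.46, 0.50),
        "S/Total": (None,) * 21,
    },
    "sidechain": {
        "O": (0, 0, 0, 0, 0, 0, 0, 0, 44, 0, 75, 19, 0, 0, 0, 38, 108, 42, 77, 0, 0),
        "N": (0, 0, 0, 0, 0, 0, 0, 0, 0, 20, 0, 0, 0, 56, 43, 53, 0, 38, 0, 23, 57),
        "C": (119, 133, 114, 121, 23, 71, 75, 0, 48, 95, 29, 90, 130, 64, 67, 18, 23, 16, 13, 64, 36),
        "S": (0, 0, 0, 0, 93, 28, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
        "Total": (119, 133, 114, 121, 116, 99, 75, None, 92, 115, 104, 109, 130, 120, 110, 109, 131, 96, 90, 87, 93),
        "O,N/Total": (None, None, None, None, None, None, None, None, 0.48, 0.17, 0.72, 0.17, None, 0.47, 0.39, 0.83, 0.82, 0.83, 0.86, 0.26, 0.61),
        "C/Total": (1.00, 1.00, 1.00, 1.00, 0.20, 0.72, 1.00, None, 0.52, 0.83, 0.28, 0.83, 1.00, 0.53, 0.61, 0.17, 0.18, 0.17, 0.14, 0.74, 0.39),
        "S/Total": (None, None, None, None, 0.80, 0.28, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None),
    },
}

PDB_3RING = {
    "combined": {
        "O": (3514, 5045, 6504, 3003, 918, 1260, 7254, 8653, 13110, 1237, 14400, 8618, 5832, 1853, 8862, 29681, 10018, 28546, 5174, 4405),
        "N": (377, 698, 925, 453, 133, 265, 1259, 1912, 631, 656, 904, 357, 92, 3733, 3708, 1305, 4531, 1038, 8825, 10522),
        "C": (591, 813, 980, 578, 33, 338, 1035, 590, 924, 345, 418, 501, 1627, 785, 450, 351, 329, 776, 1505, 882),
        "S": (0, 0, 0, 0, 146, 107, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
        "Total": (4482, 6556, 8409, 4034, 1230, 1970, 9548, 11155, 14665, 2238, 15722, 9476, 7551, 6371, 13020, 31337, 14878, 30360, 15504, 15809),
        "O,N/Total": (0.87, 0.88, 0.88, 0.86, 0.85, 0.77, 0.89, 0.95, 0.94, 0.85, 0.97, 0.95, 0.78, 0.88, 0.97, 0.99, 0.98, 0.97, 0.90, 0.94),
        "C/Total": (0.13, 0.12, 0.12, 0.14, 0.03, 0.17, 0.11, 0.05, 0.06, 0.15, 0.03, 0.05, 0.22, 0.12, 0.03, 0.01, 0.02, 0.03, 0.10, 0.06),
        "S/Total": (None, None, None, None, 0.12, 0.05, None, None, None, None, None, None, None, None, None, None, None, None, None, None),
    },
    "backbone": {
        "O": (3514, 5045, 6504, 3003, 918, 1260, 7254, 8653, 4959, 1237, 5402, 2765, 5832, 1853, 3062, 5656, 3866, 5005, 5174, 4405),
        "N": (377, 698, 925, 453, 133, 265, 1259, 1912, 631, 141, 904, 357, 92, 298, 572, 1305, 882, 1038, 883, 625),
        "C": (13, 25, 38, 18, 6, 13, 176, 590, 42, 10, 88, 22, 95, 38, 38, 61, 56, 62, 52, 68),
        "S": (0,) * 20,
        "Total": (3904, 5768, 7467, 3474, 1057, 1538, 8689, 11155, 5632, 1388, 6394, 3144, 6019, 2189, 3672, 7022, 4804, 6105, 6109, 5098),
        "O,N/Total": (1.00, 1.00, 0.99, 0.99, 0.99, 0.99, 0.98, 0.95, 0.99, 0.99, 0.99, 0.99, 0.98, 0.98, 0.99, 0.99, 0.99, 0.99, 0.99, 0.99),
        "C/Total": (0.00, 0.00, 0.01, 0.01, 0.01, 0.01, 0.02, 0.05, 0.01, 0.01, 0.01, 0.01, 0.02, 0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01),
        "S/Total": (None,) * 20,
    },
    "sidechain": {
        "O": (0, 0, 0, 0, 0, 0, 0, 0, 8151, 0, 8998, 5853, 0, 0, 5800, 24025, 6152, 23541, 0, 0),
        "N": (0, 0, 0, 0, 0, 0, 0, 0, 0, 515, 0, 0, 0, 3435, 3136, 0, 3649, 0, 7942, 9897),
        "C": (578, 788, 942, 560, 27, 325, 859, 0, 882, 335, 330, 479, 1532, 747, 412, 290, 273, 714, 1453, 814),
        "S": (0, 0, 0, 0, 146, 107, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
        "Total": (578, 788, 942, 560, 173, 432, 859, None, 9033, 850, 9328, 6332, 1532, 4182, 9348, 24315, 10074, 24255, 9395, 10711),
        "O,N/Total": (None, None, None, None, None, None, None, None, 0.90, 0.61, 0.96, 0.92, None, 0.82, 0.96, 0.99, 0.97, 0.97, 0.85, 0.92),
        "C/Total": (1.00, 1.00, 1.00, 1.00, 0.16, 0.75, 1.00, None, 0.10, 0.39, 0.04, 0.08, 1.00, 0.18, 0.04, 0.01, 0.03, 0.03, 0.15, 0.08),
        "S/Total": (None, None, None, None, 0.84, 0.25, None, None, None, None, None, None, None, None, None, None, None, None, None, None),
    },
}
# fmt: on

SURVEYS = {"md": (MD_3RING, MD_RESIDUES), "pdb": (PDB_3RING, PDB_RESIDUES)}


def counts_table(survey: str, scope: str) -> CountsTable:
    """The per-class counts of one reference table as a CountsTable."""
    data, residues = SURVEYS[survey]
    table = data[scope]
    per_residue = {
        res: {cls: table[cls][i] for cls in ("O", "N", "C", "S")}
        for i, res in enumerate(residues)
    }
    return CountsTable.from_class_counts(
        per_residue,
        scope=scope,
        ring_size=3,
        criterion_tag="energy" if survey == "md" else "distance",
    )


def printed_vs_recomputed(survey: str, scope: str) -> list[dict]:
    """Compare every printed Total/ratio cell against the value
    recomputed from the per-class counts.

    Returns one record per (row, residue) cell with the printed value,
    the recomputed value, and whether they match exactly at printed
    precision.  A printed blank matches a zero numerator / zero total.
    """
    data, residues = SURVEYS[survey]
    table = data[scope]
    ct = counts_table(survey, scope)
    totals = ct.totals
    ratios = ct.rounded_ratios()
    numerators = {
        "O,N/Total": ct.counts.loc["O"] + ct.counts.loc["N"],
        "C/Total": ct.counts.loc["C"],
        "S/Total": ct.counts.loc["S"],
    }
    records = []
    for i, res in enumerate(residues):
        printed_total = table["Total"][i]
        recomputed_total: float | None = int(totals[res])
        if recomputed_total == 0:
            recomputed_total = None
        records.append(
            {
                "row": "Total",
                "residue": res,
                "printed": printed_total,
                "recomputed": recomputed_total,
                "match": printed_total == recomputed_total,
            }
        )
        for row in ("O,N/Total", "C/Total", "S/Total"):
            printed = table[row][i]
            if totals[res] == 0 or numerators[row][res] == 0:
                recomputed = None
            else:
                recomputed = float(ratios.at[row, res])
            match = (
                printed is None and recomputed is None
                or printed is not None
                and recomputed is not None
                and abs(printed - recomputed) < 1e-12
            )
            records.append(
                {
                    "row": row,
                    "residue": res,
                    "printed": printed,
                    "recomputed": recomputed,
                    "match": match,
                }
            )
    return records
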