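"""Curated reference data for the packaged apoptosis network.

The seventeen singleton attractors of the 21-vertex network: basin size,
input condition, state string (canonical vertex order), fate label and
stability class.  Basins within one input condition partition the 2^19
assignments of the free vertices.
"""

# (attractor_no, basin, GF, FasL, state_string, fate, stability)
ATTRACTOR_TABLE = [
    (1, 524288, 0, 0, "111111110010010011100", "apoptosis", "stable"),
    (2, 309976, 1, 0, "000000001101101110001", "survival", "stable"),
    (3, 186784, 1, 0, "111111110101101111101", "apoptosis", "stable"),
    (4, 524288, 0, 1, "111111110010010011110", "apoptosis", "stable"),
    (5, 476871, 1, 1, "111111110101101111111", "apoptosis", "stable"),
    (6, 5117, 1, 1, "100100001101101110011", "survival", "stable"),
    (7, 11859, 1, 1, "100111111101101111111", "repair", "stable"),
    (8, 3482, 1, 1, "000000001101101110011", "survival", "stable"),
    (9, 621, 1, 1, "110111111101101111111", "repair", "stable"),
    (10, 23520, 1, 0, "111111110100101111101", "apoptosis", "transient"),
    (11, 816, 1, 0, "011011110100101111101", "survival", "transient"),
    (12, 2712, 1, 0, "011011110101101111101", "survival", "transient"),
    (13, 336, 1, 0, "000011111101101111101", "survival", "transient"),
    (14, 144, 1, 0, "010011111101101111101", "survival", "transient"),
    (15, 48, 1, 1, "000011111101101111111", "survival", "transient"),
    (16, 18, 1, 1, "010011111101101111111", "survival", "transient"),
    (17, 26272, 1, 1, "111111110100101111111", "apoptosis", "transient"),
]

VERTEX_ORDER = ["CASP8", "CASP9", "CASP3", "BID", "BAX", "CYTC", "SMAC",
                "APAF", "IAP", "AKT", "BAD", "BCL2", "IKK", "IKB", "NFKB",
                "CFLIP", "MDM2", "P53", "DNADAM", "FASL", "GF"]


def rows_for(gf, fasl):
    return [r for r in ATTRACTOR_TABLE if r[2] == gf and r[3] == fasl]
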