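"""Bundled example dataset: blind-evaluation grades and H&E morphometry
of five rat carotid artery tissues, measured on virtually stained (VS)
and histologically stained (HS) sections.

These printed measurements are inputs to the reporting layer
(``virtstain.morphometry``): per-tissue mean +/- SD of intima thickness
(IT, um), intima area (IA, um^2) and media area (MA, um^2) for both
methods, the published relative-error (RE, %) and intima-to-media ratio
(IMR) cells for cross-checking, and the 1-5 grades three pathologists
assigned to the neointima (NI), media (M) and elastic lamina (EL)
features.
"""

from __future__ import annotations

__all__ = [
    "HE_MORPHOMETRY",
    "PRINTED_RE",
    "PRINTED_IMR",
    "BLIND_GRADES",
    "PRINTED_GRADE_AVERAGES",
    "TISSUES",
    "FEATURES",
    "METHODS",
]

TISSUES = (1, 2, 3, 4, 5)
METHODS = ("VS", "HS")
FEATURES = ("NI", "M", "EL")

# per tissue and method: quantity -> (mean, sd); IT in um, IA/MA in um^2
HE_MORPHOMETRY: dict[int, dict[str, dict[str, tuple[float, float]]]] = {
    1: {"VS": {"IT": (228.5, 0.9), "IA": (261474.5, 2253.0), "MA": (175412.1, 7082.3)},
        "HS": {"IT": (228.1, 1.9), "IA": (263530.1, 1136.2), "MA": (169753.7, 3665.8)}},
    2: {"VS": {"IT": (244.6, 1.3), "IA": (128655.6, 5884.7), "MA": (149911.9, 7493.7)},
        "HS": {"IT": (248.5, 1.9), "IA": (134151.7, 1535.5), "MA": (150026.1, 2436.2)}},
    3: {"VS": {"IT": (206.9, 2.9), "IA": (259228.6, 15163.9), "MA": (183164.8, 14245.2)},
        "HS": {"IT": (206.6, 1.1), "IA": (258425.0, 14351.3), "MA": (175953.6, 7619.6)}},
    4: {"VS": {"IT": (140.0, 1.4), "IA": (254563.0, 12650.4), "MA": (205179.6, 10924.2)},
        "HS": {"IT": (137.9, 2.0), "IA": (264064.6, 8300.7), "MA": (181998.4, 5369.6)}},
    5: {"VS": {"IT": (223.6, 2.5), "IA": (128244.5, 1436.1), "MA": (162862.3, 4462.2)},
        "HS": {"IT": (226.1, 0.7), "IA": (135838.3, 414.6), "MA": (164876.6, 1722.3)}},
}

# published RE cells (%), one decimal, keyed (tissue, quantity).
# The tissue-4 IT cell does not reproduce from the VS/HS means under
# |VS - HS| / HS x 100 (which gives 1.5); the reporting layer flags it.
PRINTED_RE: dict[tuple[int, str], float] = {
    (1, "IT"): 0.2, (1, "IA"): 0.8, (1, "MA"): 3.3,
    (2, "IT"): 1.6, (2, "IA"): 4.1, (2, "MA"): 0.1,
    (3, "IT"): 0.1, (3, "IA"): 0.3, (3, "MA"): 4.1,
    (4, "IT"): 1.6, (4, "IA"): 3.6, (4, "MA"): 12.7,
    (5, "IT"): 1.1, (5, "IA"): 5.6, (5, "MA"): 1.2,
}
KNOWN_RE_DISCREPANCIES = {(4, "IT")}

# published IMR cells (two decimals), keyed (tissue, method)
PRINTED_IMR: dict[tuple[int, str], float] = {
    (1, "VS"): 1.49, (1, "HS"): 1.55,
    (2, "VS"): 0.86, (2, "HS"): 0.89,
    (3, "VS"): 1.42, (3, "HS"): 1.47,
    (4, "VS"): 1.24, (4, "HS"): 1.45,
    (5, "VS"): 0.79, (5, "HS"): 0.82,
}

# blind-evaluation grades, keyed (tissue, method, feature):
# (pathologist 1, pathologist 2, pathologist 3), each 1-5
BLIND_GRADES: dict[tuple[int, str, str], tuple[int, int, int]] = {
    (1, "VS", "NI"): (3, 3, 4), (1, "VS", "M"): (3, 3, 4), (1, "VS", "EL"): (3, 3, 4),
    (1, "HS", "NI"): (4, 3, 4), (1, "HS", "M"): (4, 4, 4), (1, "HS", "EL"): (3, 4, 4),
    (2, "VS", "NI"): (3, 3, 4), (2, "VS", "M"): (4, 4, 4), (2, "VS", "EL"): (3, 3, 4),
    (2, "HS", "NI"): (4, 3, 4), (2, "HS", "M"): (4, 4, 4), (2, "HS", "EL"): (4, 3, 4),
    (3, "VS", "NI"): (3, 3, 4), (3, "VS", "M"): (3, 4, 5), (3, "VS", "EL"): (3, 3, 4),
    (3, "HS", "NI"): (4, 4, 4), (3, "HS", "M"): (4, 4, 5), (3, "HS", "EL"): (4, 3, 4),
    (4, "VS", "NI"): (3, 3, 4), (4, "VS", "M"): (3, 4, 4), (4, "VS", "EL"): (3, 3, 4),
    (4, "HS", "NI"): (4, 4, 5), (4, "HS", "M"): (3, 4, 4), (4, "HS", "EL"): (4, 3, 4),
    (5, "VS", "NI"): (3, 3, 4), (5, "VS", "M"): (3, 3, 4), (5, "VS", "EL"): (3, 3, 4),
    (5, "HS", "NI"): (4, 3, 5), (5, "HS", "M"): (4, 4, 5), (5, "HS", "EL"): (4, 3, 4),
}

# published two-decimal grade averages, keyed (tissue, method, feature)
PRINTED_GRADE_AVERAGES: dict[tuple[int, str, str], float] = {
    (1, "VS", "NI"): 3.33, (1, "VS", "M"): 3.33, (1, "VS", "EL"): 3.33,
    (1, "HS", "NI"): 3.67, (1, "HS", "M"): 4.00, (1, "HS", "EL"): 3.67,
    (2, "VS", "NI"): 3.33, (2, "VS", "M"): 4.00, (2, "VS", "EL"): 3.33,
    (2, "HS", "NI"): 3.67, (2, "HS", "M"): 4.00, (2, "HS", "EL"): 3.67,
    (3, "VS", "NI"): 3.33, (3, "VS", "M"): 4.00, (3, "VS", "EL"): 3.33,
    (3, "HS", "NI"): 4.00, (3, "HS", "M"): 4.33, (3, "HS", "EL"): 3.67,
    (4, "VS", "NI"): 3.33, (4, "VS", "M"): 3.67, (4, "VS", "EL"): 3.33,
    (4, "HS", "NI"): 4.33, (4, "HS", "M"): 3.67, (4, "HS", "EL"): 3.67,
    (5, "VS", "NI"): 3.33, (5, "VS", "M"): 3.33, (5, "VS", "EL"): 3.33,
    (5, "HS", "NI"): 4.00, (5, "HS", "M"): 4.33, (5, "HS", "EL"): 3.67,
}
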