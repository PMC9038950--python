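"""The curated 72-gene plastid protein-coding panel and gene-name normalization.

Complete land-plant plastomes carry ~79 widely shared protein-coding genes.
Seven of them (ndhF, psaA, psaB, rpoB, rpoC1, rpoC2, ycf2) are routinely
mis-annotated or absent from annotation sets and are excluded from the working
panel, leaving the 72 genes every downstream analysis operates on.

Gene families used for grouped loss reports are explicit lists rather than
name-prefix matches, so e.g. psaJ never falls into a "psb" bucket.
"""

from __future__ import annotations

import re

#: Genes excluded from the working panel and dropped unconditionally when
#: building phylogenomic matrices.
EXCLUDED_GENES = frozenset(
    {"ndhF", "psaA", "psaB", "rpoB", "rpoC1", "rpoC2", "ycf2"}
)

#: The 72-gene working panel, grouped by function for readability.
PANEL_72: tuple[str, ...] = (
    # photosystem II
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
    "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ",
    # ATP synthase
    "atpA", "atpB", "atpE", "atpF", "atpH", "atpI",
    # NADH dehydrogenase-like complex (ndhF excluded)
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhG", "ndhH", "ndhI",
    "ndhJ", "ndhK",
    # cytochrome b6f and related
    "petA", "petB", "petD", "petG", "petL", "petN",
    # photosystem I (psaA/psaB excluded)
    "psaC", "psaI", "psaJ",
    # large ribosomal subunit
    "rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32",
    "rpl33", "rpl36",
    # RNA polymerase (rpoB/C1/C2 excluded)
    "rpoA",
    # small ribosomal subunit
    "rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14",
    "rps15", "rps16", "rps18", "rps19",
    # other conserved genes
    "rbcL", "matK", "ccsA", "cemA", "clpP", "infA", "accD",
    "ycf1", "ycf3", "ycf4",
)

assert len(PANEL_72) == 72
assert not EXCLUDED_GENES & set(PANEL_72)

#: Curated synonym table (lowercased raw -> canonical panel symbol), covering
#: the common alternative symbols seen in GenBank plastome annotations.
SYNONYMS: dict[str, str] = {
    "pbf1": "psbN",
    "ycf9": "psbZ",
    "lhba": "psbZ",
    "psbg": "ndhK",
    "ycf14": "matK",
    "clpp1": "clpP",
    "tic214": "ycf1",
    "ycf5": "ccsA",
    "ycf10": "cemA",
    "frxb": "ndhI",
    "zfpa": "accD",
    "infa-like": "infA",
}

#: Explicit functional gene families (used by loss reports); prefix guessing
#: is deliberately avoided.
GENE_FAMILIES: dict[str, tuple[str, ...]] = {
    "ndh": ("ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhG", "ndhH",
            "ndhI", "ndhJ", "ndhK"),
    "psb": ("psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
            "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ"),
    "psa": ("psaC", "psaI", "psaJ"),
    "atp": ("atpA", "atpB", "atpE", "atpF", "atpH", "atpI"),
    "pet": ("petA", "petB", "petD", "petG", "petL", "petN"),
    "rpl": ("rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32",
            "rpl33", "rpl36"),
    "rps": ("rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12",
            "rps14", "rps15", "rps16", "rps18", "rps19"),
}

#: Conserved vs non-conserved photosystem-II gene groups whose GC contrast is
#: a standing comparison in plastome studies.
CONSERVED_PSB = ("psbB", "psbT", "psbN", "psbH")
NONCONSERVED_PSB = ("psbA", "psbI", "psbK", "psbL")

#: Six focal genes whose presence inside the inverted repeats is tracked.
FOCAL_IR_GENES = ("rps19", "rpl2", "rpl23", "ndhB", "rps7", "rps12")

#: Controlled vocabulary for the 14 major Viridiplantae lineages.
MAJOR_CLADES: tuple[str, ...] = (
    "chlorophytes", "charophytes", "liverworts", "mosses", "hornworts",
    "lycophytes", "ferns", "gymnosperms", "basal_angiosperms", "magnoliids",
    "Chloranthales", "monocots", "Ceratophyllales", "eudicots",
)

_LOOKUP: dict[str, str] = {g.lower(): g for g in PANEL_72}
_LOOKUP.update(SYNONYMS)

# copy/fragment designators sometimes appended to gene symbols: psbA_1,
# rpl2-A, ndhB.2, rps12_copy2 ...
_SUFFIX_RE = re.compile(r"(?:[_\-.](?:copy)?\d+|[_\-][a-dA-D])$")


def normalize_gene_name(raw: str) -> str | None:
    """Map a raw annotation symbol onto the 72-gene panel.

    Matching is case-insensitive and goes through a curated synonym table;
    trailing copy/fragment designators are stripped only when the bare symbol
    is not itself a panel name. Returns ``None`` (REJECT) for symbols outside
    the panel — rejected genes take no part in any analysis.

    Raises ``ValueError`` on an empty string.
    """
    if not raw or not raw.strip():
        raise ValueError("empty gene name")
    key = raw.strip().lower()
    hit = _LOOKUP.get(key)
    if hit is not None:
        return hit
    stripped = _SUFFIX_RE.sub("", key)
    if stripped != key:
        return _LOOKUP.get(stripped)
    return None
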