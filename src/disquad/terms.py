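"""Bundled ontology-term category table.

DisProt annotates regions with identifiers from three ontologies:

* **IDPO** — disorder-specific structural states, transitions and entropic
  functions;
* **GO** — molecular functions;
* **ECO** — the experimental evidence behind the annotation.

IDPO mixes structural-state, transition and function terms under one
namespace, so a small lookup table is needed to place each identifier in
the right category.  The table below covers the terms this pipeline's
analyses name explicitly; unknown IDPO identifiers default to the
structural-state category (with a warning), unknown GO identifiers to the
function category.
"""

from __future__ import annotations

import warnings

#: category labels
STRUCTURAL_STATE = "structural_state"
TRANSITION = "transition"
FUNCTION = "function"
EVIDENCE = "evidence"

#: IDPO structural-state terms (disorder flavours).
STRUCTURAL_STATE_TERMS: dict[str, str] = {
    "IDPO:00076": "disorder",
    "IDPO:00077": "molten globule",
    "IDPO:00078": "pre-molten globule",
}

#: IDPO structural-transition terms.
TRANSITION_TERMS: dict[str, str] = {
    "IDPO:00050": "structural transition",
    "IDPO:00051": "disorder to order transition",
    "IDPO:00052": "order to disorder transition",
}

#: Function terms (IDPO entropic-chain terms plus the GO terms the
#: enrichment analyses single out; any other GO id is also a function term).
FUNCTION_TERMS: dict[str, str] = {
    "IDPO:00502": "flexible linker/spacer",
    "GO:0005515": "protein binding",
    "GO:0060090": "molecular adaptor activity",
    "GO:0098772": "molecular function regulator",
}

#: ECO evidence terms named in the analyses (informational only; every
#: ECO:* id is treated as evidence).
EVIDENCE_TERMS: dict[str, str] = {
    "ECO:0006220": "X-ray crystallography",
    "ECO:0006165": "NMR spectroscopy",
    "ECO:0006204": "circular dichroism",
    "ECO:0006224": "cryo-EM",
    "ECO:0007691": "proteolysis assay",
}


def categorize_term(term_id: str) -> str:
    """Return the category (structural_state/transition/function/evidence)
    of an ontology identifier.

    Unknown IDPO ids fall back to structural_state, unknown GO ids to
    function; an unrecognized namespace is kept as a function term.  All
    fallbacks emit a warning.
    """
    if term_id.startswith("ECO:"):
        return EVIDENCE
    if term_id in STRUCTURAL_STATE_TERMS:
        return STRUCTURAL_STATE
    if term_id in TRANSITION_TERMS:
        return TRANSITION
    if term_id in FUNCTION_TERMS:
        return FUNCTION
    if term_id.startswith("IDPO:"):
        warnings.warn(
            f"unknown IDPO term {term_id}: treating as structural state",
            stacklevel=2,
        )
        return STRUCTURAL_STATE
    if term_id.startswith("GO:"):
        return FUNCTION
    warnings.warn(
        f"unknown term namespace for {term_id}: keeping as function term",
        stacklevel=2,
    )
    return FUNCTION


def term_namespace(term_id: str) -> str:
    """The ontology namespace prefix (``ECO``, ``IDPO``, ``GO``, ...)."""
    return term_id.split(":", 1)[0]
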