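"""Published EMT reference data used by the worked examples.

The signature for TGF-β1-induced epithelial–mesenchymal transition consists
of eight topologically selected markers plus the clamped inducer.  The
prototypal mesenchymal configurations set each marker to 1 if it is
upregulated by TGF-β1 induction in the corresponding cell line (bulk
RNA-seq, GEO accession GSE90566) and 0 if downregulated; the inducer and
FOXO6 (not quantified in that dataset) are omitted from the references and
are therefore masked in distance computations.

``HIGH_EFFICIENCY_PHENOTYPES`` lists the expression patterns of the eight
TGF-β1-expressing phenotypes reported to have high transformation
efficiency, keyed by their published phenotype ids; they decompose into
four couples differing only in FOXO6.
"""

from __future__ import annotations

from .analysis import ReferenceState

# signature order used by the published phenotype patterns
SIGNATURE_GENES: tuple[str, ...] = (
    "TGFB1",
    "BAMB1",
    "CBLC",
    "EGFR",
    "ERBB2",
    "FOXO6",
    "ITGB1",
    "MAPK1",
    "TLR2",
)

# high-transformation-efficiency phenotypes (pattern over SIGNATURE_GENES)
HIGH_EFFICIENCY_PHENOTYPES: dict[int, tuple[int, ...]] = {
    7:   (1, 0, 0, 0, 0, 0, 0, 0, 0),
    248: (1, 0, 0, 0, 0, 1, 0, 0, 0),
    13:  (1, 0, 1, 0, 0, 0, 0, 0, 0),
    291: (1, 0, 1, 0, 0, 1, 0, 0, 0),
    24:  (1, 0, 0, 0, 1, 0, 0, 0, 0),
    348: (1, 0, 0, 0, 1, 1, 0, 0, 0),
    77:  (1, 0, 1, 0, 1, 0, 0, 0, 0),
    343: (1, 0, 1, 0, 1, 1, 0, 0, 0),
}

_REFERENCE_GENES = ("BAMB1", "CBLC", "EGFR", "ERBB2", "ITGB1", "MAPK1", "TLR2")

#: prototypal mesenchymal configuration, A549 (lung adenocarcinoma)
A549_MESENCHYMAL = ReferenceState(_REFERENCE_GENES, (1, 0, 1, 0, 1, 1, 1))

#: prototypal mesenchymal configuration, Panc1 (pancreatic ductal adenocarcinoma)
PANC1_MESENCHYMAL = ReferenceState(_REFERENCE_GENES, (0, 0, 0, 0, 1, 0, 1))
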