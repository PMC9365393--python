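"""Published worked-example inputs for the pipeline's metric layer.

Small literature-derived tables used as inputs by the analysis drivers and
the reproduction script: buried areas of the first and last translated
interfaces for five yeast multi-interface heteromeric subunits known to
assemble cotranslationally in the sequential mode, and the early/late
contingency counts of simultaneously forming versus other heteromeric
interfaces in predicted assembly pathways.
"""

#: (nascent chain, mature partner, first-interface Å², last-interface Å²)
SEQUENTIAL_YEAST_SUBUNITS = [
    ("Set1", "uncertain", 1467.0, 1025.0),
    ("Fas2", "Fas1", 4226.0, 484.0),
    ("Pfk1", "Pfk2", 7796.0, 5749.0),
    ("Gcn3", "Gcd2", 1210.0, 687.0),
    ("Rpt2", "Rpt1", 4226.0, 484.0),
]

#: 2x2 counts of early-forming interfaces: rows are (cotranslationally
#: forming, all other heteromeric), columns (early, late).
EARLY_LATE_TABLE = ((180, 90), (633, 538))
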