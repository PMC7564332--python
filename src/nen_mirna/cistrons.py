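"""Curated cistron membership for the most abundant lung-NEN miRNA clusters.

Membership follows the genomic organization of the human miRNA clusters:
cluster-mir-98 groups the 13 co-transcribed let-7-family loci,
cluster-mir-143 pairs miR-143 with miR-145, and the miR-375 and miR-21
clusters are monocistronic.
"""

from nen_mirna.core_io import CistronMap

LUNG_NEN_CISTRONS = CistronMap(
    {
        "cluster-mir-98": [
            "miR-125b-1",
            "let-7a-2",
            "miR-100",
            "miR-99a",
            "let-7c",
            "miR-125b-2",
            "let-7a-3",
            "let-7b",
            "let-7a-1",
            "let-7f-1",
            "let-7d",
            "miR-98",
            "let-7f-2",
        ],
        "cluster-mir-375": ["miR-375"],
        "cluster-mir-21": ["miR-21"],
        "cluster-mir-143": ["miR-143", "miR-145"],
    }
)
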