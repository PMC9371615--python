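"""Hypergeometric over-representation of annotation terms.

A toy background of 10 proteins with one term annotating 4 of them; a
5-protein selection containing all 4 annotated proteins is unlikely by
chance: p = C(4,4) * C(6,1) / C(10,5) = 6/252 = 0.0238.
"""

from phosphodiff import AnnotationMap, enrich_terms

background = [f"P{i}" for i in range(10)]
annotations = AnnotationMap(
    protein_to_terms={f"P{i}": {"GO:0006915"} for i in range(4)},
    term_names={"GO:0006915": "apoptotic process"},
)
selected = ["P0", "P1", "P2", "P3", "P9"]

result = enrich_terms(selected, background, annotations, alpha=0.05)
print(result.to_string(index=False))
print(
    "\nk of the n selected proteins carry the term, K of the N background "
    "proteins do; p is the upper-tail hypergeometric probability of drawing "
    "at least k annotated proteins, and q its Benjamini-Hochberg adjustment."
)
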