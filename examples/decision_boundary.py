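"""The quadratic decision boundary on two hard homolog pairs.

Both pairs have Neighborhood Correlation below the classic 0.5 homology
threshold, so a similarity-only caller would reject them.  Strong synteny
correlation pushes them over the boundary h = NC^2 + 0.25 SyC^2 - 0.25 > 0.
"""

from genfamclust import decision_value

pairs = [
    # (name, NC, SyC): a multidomain receptor pair and a highly divergent
    # peptidase pair, both rescued by conserved gene neighborhoods
    ("TNFR-family pair (domain insertion)", 0.351, 0.983),
    ("USP-family pair (high divergence)", 0.411, 0.672),
]

for name, nc, syc in pairs:
    h = decision_value(nc, syc)
    verdict = "homolog" if h > 0 else "non-homolog"
    print(f"{name}: NC={nc}, SyC={syc} -> h={h:.3f} ({verdict})")
    print(f"  similarity alone: NC={nc} <= 0.5 -> non-homolog")

print()
print("h > 0 calls a pair homologous; with SyC = 0 the rule is exactly |NC| > 0.5.")
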