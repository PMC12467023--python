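"""Call sex-bias directions for a handful of published-style FPKM pairs.

Each row is one gene's expression in male and female samples (FPKM). The
caller reports a direction (male / female / unbiased), the pseudocounted
fold change, and whether the gene cleared the expression floor.
"""

from sbgturnover import CallParams, call_bias

ROWS = [
    # (gene, species, male FPKM, female FPKM)
    ("LOC663373", "Tcast", 59.295, 1.458),     # beetle gonad, strongly male
    ("Aste1435_g", "Astep", 27.62, 73.823),    # mosquito whole body
    ("AALB006416", "Aalbi", 104.623, 122.974), # weak female bias, ratio 1.18
    ("KWMTBOMO04424", "Bmori", 63.89, 228.915),
    ("low_expr", "Dmel", 0.5, 0.9),            # below the 1-FPKM floor
]

params = CallParams()  # floor 1.0 FPKM, sign-based threshold
print(f"{'gene':<16}{'species':<9}{'direction':<11}{'fold':>8}  floor")
for gene, sp, m, f in ROWS:
    call = call_bias(m, f, params, gene_id=gene, species_id=sp)
    print(
        f"{gene:<16}{sp:<9}{call.direction:<11}{call.fold_change:>8.2f}"
        f"  {'pass' if call.passed_floor else 'FAIL'}"
    )
print()
print("fold is max(m,f)+eps over min(m,f)+eps; a direction is only assigned")
print("when the larger sex clears the floor and the ratio meets the threshold.")
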