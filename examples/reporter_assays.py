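"""Small reporter-assay quantifications.

Background-subtracted class-switching percentages, competitive-growth
ratio normalisation, nuclear-signal fractions and gammaH2AX foci
thresholding — the scalar summaries used around the main assays.
"""

from aidlicense import (
    background_subtracted_percent,
    competitive_growth,
    foci_positive_fraction,
    nuclear_fraction,
)

csr, floored = background_subtracted_percent(24.0, 1.5)
print(f"CSR: 24.0% IgA+ with 1.5% empty-vector background -> {csr:.1f}%")

series = competitive_growth([0.80, 0.74, 0.51, 0.22], mode="relative_day0")
print("competitive growth (GFP+/GFP- vs day 0):",
      [f"{x:.2f}" for x in series])

print(f"nuclear fraction: 380/1450 signal units -> "
      f"{nuclear_fraction(380, 1450):.1f}% nuclear")

foci = [0, 1, 7, 2, 12, 5, 0, 3, 9, 1]
print(f"cells with >=5 gammaH2AX foci: "
      f"{foci_positive_fraction(foci, k=5):.0f}% of {len(foci)} cells")

# Each value is the per-cell or per-culture statistic that the grouped,
# reference-normalised figures are built from.
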