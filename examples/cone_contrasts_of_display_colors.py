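"""Cone contrasts and opponent responses of the nine display stimuli.

Builds the isoluminant stimulus table (printed CIE xy chromaticities at
9.5 cd/m^2), converts each color to cone excitations through the configured
XYZ->LMS matrix, and prints the Weber contrasts against the adaptation gray
plus the two opponent-channel responses.  Blue should carry the most
negative R_LM and R_Y of the set — that is what anchors the "negative"
response cluster in the imaging analysis.
"""

from warmcool.synthetic import stimulus_table

table = stimulus_table(pink="K1")
print(table[["label", "x", "y", "C_L", "C_M", "C_S", "R_LM", "R_Y"]]
      .to_string(index=False, float_format=lambda v: f"{v:+.4f}"))

most_negative = table.set_index("label")["R_LM"].idxmin()
print(f"\nmost negative L-M contrast: {most_negative}"
      " (the cluster anchor in the imaging analysis)")
print("colors with sign(R_Y) != sign(R_LM):",
      ", ".join(table.loc[(table.R_LM > 0) != (table.R_Y > 0), "label"]))
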