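"""Relative invasion from synthetic liver sections.

Each section has a liver spanning a known depth and a lesion front of a
known maximal depth from the capsule edge; the relative invasion
RI = invaded depth / total depth recovers the generating ratio exactly.
"""

from methmorph import generate_section, relative_invasion

for total, lesion in [(120, 30), (120, 60), (120, 90), (120, 0)]:
    section = generate_section(total, lesion, width_px=100, seed=lesion)
    res = relative_invasion(section)
    print(
        f"liver depth {res.total_depth:>3} px, lesion depth {res.invaded_depth:>3} px"
        f" -> RI = {res.relative_invasion:.2f} (expected {lesion / total:.2f})"
    )
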