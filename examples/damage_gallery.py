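"""Apply every damage simulator to one synthetic digit glyph.

Damage is non-blind: each simulator returns both the damaged image and the
boolean mask of overwritten cells, which becomes the inpainting domain.
"""

from chinpaint import (
    damage_customized,
    damage_random_pixels,
    damage_random_rows,
    make_glyph_dataset,
)

images, labels = make_glyph_dataset(1, seed=0)
digit = images[8]  # a rendered "8"

for kind in "ABCD":
    res = damage_customized(digit, kind)
    print(f"customized {kind}: {res.n_damaged:4d} cells overwritten ({res.kind})")

res = damage_random_rows(digit, k=10, seed=42)
print(f"random rows k=10: {res.n_damaged:4d} cells (10 whole rows of 28)")

res = damage_random_pixels(digit, p=0.5, seed=42)
print(f"random pixels p=0.5: {res.n_damaged:4d} cells (half of 784)")

# Every damaged cell is set to mid-grey (intensity 128, phase ~0 — neither
# ink nor background); unmasked cells are byte-identical to the input.
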