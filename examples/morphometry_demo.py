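"""Nuclear morphometry: volume, surface, compactness, flatness, elongation.

Measures three synthetic nuclei that mimic the imaged populations: a round
nucleus, a flattened one, and an elongated one.
"""

from nucpattern import PhantomSpec, make_mask, measure_nucleus

shapes = {
    "round (r = 4 µm)": PhantomSpec(shape="sphere", semi_axes=(4.0,) * 3,
                                    spacing=(0.1, 0.1, 0.24)),
    "flattened (5, 4.5, 2 µm)": PhantomSpec(shape="ellipsoid",
                                            semi_axes=(5.0, 4.5, 2.0),
                                            spacing=(0.1, 0.1, 0.24)),
    "elongated (8, 3, 3 µm)": PhantomSpec(shape="ellipsoid",
                                          semi_axes=(8.0, 3.0, 3.0),
                                          spacing=(0.1, 0.1, 0.24)),
    "invaginated": PhantomSpec(shape="invaginated",
                               semi_axes=(4.5, 4.0, 3.5),
                               spacing=(0.1, 0.1, 0.24), n_lobes=3,
                               lobe_radius=1.8, seed=2),
}

print(f"{'nucleus':28s} {'V (µm³)':>9s} {'S (µm²)':>9s} {'C':>6s} "
      f"{'flat':>6s} {'elong':>6s}  axes")
for name, spec in shapes.items():
    rec = measure_nucleus(make_mask(spec))
    print(f"{name:28s} {rec.volume:9.0f} {rec.surface_area:9.0f} "
          f"{rec.compactness:6.3f} {rec.flatness:6.2f} {rec.elongation:6.2f}"
          f"  flattening={rec.flattening_axis} elongation={rec.elongation_axis}")
print(
    "\nCompactness 36πV²/S³ is 1 for a sphere and falls with invaginations;\n"
    "flatness = mid/short axis, elongation = long/mid axis (both 1 for a\n"
    "sphere). The flattening axis flags nuclei squeezed along the optical Z."
)
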