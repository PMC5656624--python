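"""Persistence diagrams of the three-gray-level toy images.

Builds the two block-layout fixtures (dark/mid-gray/white), computes the
dimension-0 and dimension-1 diagrams, and prints the (birth, death)
points with multiplicities.  On the components image the two bridged
dark blocks die when the mid-gray bridges enter the sublevel set, three
dark domains survive to the white background, and five mid-gray blocks
appear at the middle level; on the rings image the dark rings fill at
mid gray and the mid-gray rings fill at white.
"""

from phiscore import FixtureSpec, compute_pd0, compute_pd1, make_fixture

components = make_fixture(FixtureSpec(kind="components"))
pd0 = compute_pd0(components)
print("components fixture, PD0 (birth, death): multiplicity")
for _, row in pd0.to_dataframe().iterrows():
    print(f"  ({row.birth:3d}, {row.death:3d}): {row.multiplicity}")
# (0,128):2 bridged blocks, (0,255):3 survivors, (128,255):5 mid-gray blocks

holes = make_fixture(FixtureSpec(kind="holes"))
pd1 = compute_pd1(holes)
print("holes fixture, PD1 (birth, death): multiplicity")
for _, row in pd1.to_dataframe().iterrows():
    print(f"  ({row.birth:3d}, {row.death:3d}): {row.multiplicity}")
# (0,128):2 dark rings, (128,255):2 mid-gray rings
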