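"""Chemical-space diagnostic: ECFP fingerprints embedded with t-SNE.

Used to check whether different data sources (e.g. generated vs
experimental negatives) cover different regions of chemical space.
"""

from cocrystal_gcn import SyntheticSpec, chemspace_embedding, generate_library

donors = generate_library(SyntheticSpec(n_molecules=40, donor_fraction=1.0,
                                        acceptor_fraction=0.0, seed=1))
acceptors = generate_library(SyntheticSpec(n_molecules=40, donor_fraction=0.0,
                                           acceptor_fraction=1.0, seed=2))

df = chemspace_embedding({"donors": donors, "acceptors": acceptors}, seed=0,
                         out_csv="scratch_chemspace.csv", out_plot="scratch_chemspace.png")
print(df.groupby("set_label")[["x", "y"]].mean().round(2))
print(f"\n{len(df)} molecules embedded; coordinates in scratch_chemspace.csv, "
      "plot in scratch_chemspace.png")
# The two motif families should form visibly separated clusters because
# their circular-substructure fingerprints share few bits.
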