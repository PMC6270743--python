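"""Predict the inter-dye distance distribution of labeled dsDNA from structure.

Builds the idealized 17-bp-separation labeled duplex, computes the
sterically accessible volume of each dye (donor Alexa 488, acceptor
Alexa 647, coarse-grained per their linker geometry), and compares the
plain AV distance statistics with the weighted AV (Gaussian occupancy
centered at the attachment, ideal-chain width with b_eff = 3.6 A).  The
weighting leaves the mean almost unchanged but shrinks the predicted
width toward what lifetime measurements on rigid DNA actually show.
"""

from fretwav.structure_builder import build_construct
from fretwav.wav import (
    ACCEPTOR_ALEXA647,
    DONOR_ALEXA488,
    accessible_volume,
    interdye_distribution,
    sigma_av,
    weight_av,
)

structure, (site_d, site_a) = build_construct(17)
print(f"duplex: {len(structure)} pseudo-atoms; donor residue {site_d.residue}, "
      f"acceptor residue {site_a.residue}")

av_d = accessible_volume(structure, DONOR_ALEXA488, site_d, spacing=0.8)
av_a = accessible_volume(structure, ACCEPTOR_ALEXA647, site_a, spacing=0.8)
print(f"AV clouds: {av_d.n_points} donor points, {av_a.n_points} acceptor points")

uniform = interdye_distribution(av_d, av_a, seed=0)
print(f"plain AV:   <R_DA> = {uniform.mean:.1f} A, sigma_DA = {uniform.sigma:.1f} A")

b_eff = 3.6
w_d = weight_av(av_d, sigma_av(b_eff, DONOR_ALEXA488.l_link))
w_a = weight_av(av_a, sigma_av(b_eff, ACCEPTOR_ALEXA647.l_link))
weighted = interdye_distribution(w_d, w_a, seed=0)
print(f"wAV (b_eff={b_eff} A): <R_DA> = {weighted.mean:.1f} A, "
      f"sigma_DA = {weighted.sigma:.1f} A")
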