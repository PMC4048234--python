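"""Score one synthetic islet and compare against its ground truth.

Generates a three-channel islet image (DAPI nuclei, 488 β-marker
staining, 555 α-counterstain) with known cell classes and stained
fraction, runs the full scoring pipeline, and prints the recovered
features next to the generator's truth.
"""
import isletquant as iq

params = iq.SynthParams(seed=42, noise_sd=0.1)
stack, islet, truth = iq.generate_islet(params)
features = iq.score_islet(stack, islet)

n_beta_true = sum(1 for c in truth.cell_class if c == iq.BETA)
print(f"islet area:            {features.islet_size_px} px")
print(f"area score:            {features.area_score:.3f}  "
      f"(truth {3 * truth.true_stained_fraction:.3f} on the [0,3] scale)")
print(f"beta cells detected:   {features.n_beta}  (truth {n_beta_true})")
print(f"alpha cells detected:  {features.n_alpha}  "
      f"(truth {len(truth.cell_class) - n_beta_true})")
print(f"beta-cell density:     {features.beta_density:.2f} per 10^4 px^2")
print()
print("The area score is 3x the stained non-nuclear islet pixel fraction;")
print("a score near the truth means the adaptive k-means threshold separated")
print("staining from background correctly despite noise and illumination drift.")
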