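"""Peel a network layer into nested m-cores.

The m-core keeps every gene whose layer degree is at least m (peeling genes
below the bar and dropping drugs left without edges); increasing m exposes
the most densely drug-connected core genes.
"""

from dgnet import SyntheticSpec, build_layer, core_profile, generate_target_table, peel_decomposition

spec = SyntheticSpec(seed=11, n_drugs=50, n_genes=600)
targets, _ = generate_target_table(spec)
dtn = build_layer(targets.pairs, "target")

dec = peel_decomposition(dtn)
print(f"layer: {dec.layer}  m-core range: 1-{dec.m_max}")
print(core_profile(dec).to_string(index=False))
# Each row summarizes one peeling level: how many genes and drugs survive the
# degree bar m and how many connected components they form.  Gene counts
# shrink as m grows (cores are nested); the genes surviving at the largest m
# are the hub genes of the layer.

top = dec.cores[dec.m_max][0]
print(f"core genes at m={dec.m_max}: {sorted(top)}")
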