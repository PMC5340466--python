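"""Render a heat tree: statistics mapped to node size and color.

Node size tracks the number of observations per taxon (subtaxa included),
color tracks the same statistic on a log scale; the legend JSON records the
exact value -> aesthetic relationship so plots are machine-checkable.
"""
import json

from taxomap import FixtureConfig, HeatTreeSpec, random_taxmap, render

tm = random_taxmap(FixtureConfig(n_taxa=45, n_obs=250, n_roots=2, seed=6)).taxmap

spec = HeatTreeSpec(node_size="n_obs", node_color="n_obs",
                    node_color_transform="log10", node_label="name")
res = render(tm, spec, output="scratch_heat_tree.svg", width_px=900, height_px=900)

print("sub-trees drawn:", res.n_trees, "(one per root)")
meta = json.load(open("scratch_heat_tree.svg.legend.json"))
print("color legend ticks:", [round(t, 1) for t in meta["legend"]["node_color"]["ticks"]])
print("         -> colors:", meta["legend"]["node_color"]["tick_colors"])
print("size legend ticks :", [round(t, 1) for t in meta["legend"]["node_size"]["ticks"]])
# The tick values pass through the same mapping as the drawn nodes, so the
# legend is faithful by construction; coordinates are normalized, so the
# figure is identical at any output size.
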