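"""Parse taxonomic lineages out of free-text headers into a Taxmap.

A single regex + key drives parsing of any lineage dialect; shared prefixes
are merged into one edge list, so each taxon appears exactly once no matter
how many records cite it.
"""
from taxomap import ParseSpec, parse_records, write_lineages

headers = [
    "AB0001 k__Bacteria;p__Firmicutes;g__Bacillus",
    "AB0002 k__Bacteria;p__Firmicutes;g__Clostridium",
    "AB0003 k__Bacteria;p__Proteobacteria",
    "AB0004 k__Archaea;p__Euryarchaeota",
]
spec = ParseSpec(regex=r"(\S+) (.*)", key=("obs_info:accession", "class"),
                 rank_separator="__")
tm = parse_records(headers, spec)

print(tm)
print(tm.taxa.to_string(index=False))
print(tm.obs.to_string(index=False))
print("lineages:", write_lineages(tm, rank_separator="__"))
print("newick per root:", tm.to_newick())
# 7 unique taxa from 4 records: Bacteria/Firmicutes appear once despite being
# shared; two roots (Bacteria, Archaea) make this a forest, not a tree.
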