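"""Parse a GCT alteration table and an AUC response table, then match them.

The alteration file labels cell lines with an ``_ORGAN`` suffix while the
response table does not; matching normalizes both sides and intersects them.
"""

import io

from pharmforest import match_cell_lines, parse_alteration_gct, parse_response_table

GCT = """#1.2
3\t3
Name\tDescription\tA549_LUNG\tSKMEL2_SKIN\tHT29_LARGE_INTESTINE
BRAF_MUT\tna\t0\t1\t1
TP53_DEL\tna\t1\t0\t1
MYC_AMP\tna\t1\t1\t0
"""

RESPONSES = """Compound,A549,SKMEL2,U87
Erlotinib,0.91,0.85,0.77
Nutlin-3a,0.40,,0.62
"""

alt = parse_alteration_gct(io.StringIO(GCT))
resp = parse_response_table(io.StringIO(RESPONSES))
study = match_cell_lines(alt, resp)

print(f"alterations parsed: {alt.n_cell_lines} cell lines x {alt.n_alterations} alterations")
print(f"responses parsed:   {len(resp.cell_lines)} cell lines, {resp.n_missing} missing AUC(s)")
print(f"matched study:      {study.cell_lines} (intersection, alteration-file order)")
print(f"tissues recorded:   {study.alterations.tissue.to_dict()}")
# The matched study keeps 2 shared cell lines: HT29 is only in the alteration
# file and U87 only in the response table, so both are dropped.
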