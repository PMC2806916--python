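"""A full synthetic mat / edge / outside transect: geochemistry and clone
libraries generated together, summarized into the joint activity table, and
checked for flux-community concordance.
"""
from seepscape import concordance_check, simulate_transect, summary_frame

transect = simulate_transect(seed=0, noise_fraction=0.0, n_clones=60)

print(summary_frame(transect.rows).round(2).to_string(index=False))
print()
for res in concordance_check(transect.rows):
    frac = "n/a (all pairs tied or missing)" if res.concordant_fraction is None \
        else f"{res.concordant_fraction:.2f}"
    print(f"{res.layer:7s} {res.pairing}: concordant fraction {frac} "
          f"over {res.n_pairs_used} pairs"
          + (f", ties {res.ties}" if res.ties else ""))
# At the surface the flux ordering (mat > edge > outside) is perfectly
# concordant with the SRB and ANME clone fractions; at depth the communities
# converge (ties) even though measurable fluxes have collapsed - the
# transect's central pattern.
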