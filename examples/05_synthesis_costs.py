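"""ATP bookkeeping for the translation machinery.

Prints the cellular amino-acid flux demand, the ATP-equivalent costs of
building each machine species, and what a 1-fmol ATP investment means
relative to the cell's energy budget.
"""

from elonsim import atp_context, flux_demand, protein_cost, rna_cost, unit_costs

demand = flux_demand(ribosomes_per_cell=13_500, active_fraction=0.8, rate_aa_per_s=16.0)
print(f"protein synthesis consumes {demand:,.0f} aa/s per cell (> 170,000)")

print(f"average 76-nt tRNA: {rna_cost({b: 19 for b in 'TCAG'}):,.0f} ATP equivalents")
synthesis, translation, total = protein_cost(394, synthesis_atp=1989)
print(f"EFTu: {synthesis:,.0f} (amino acids) + {translation:,.0f} (4/bond) = {total:,.0f}")
print(f"per-molecule costs used in allocation: {unit_costs()}")

minutes, fraction = atp_context(1.0)
print(
    f"1 fmol ATP per cell = {minutes:.1f} min of ATP production "
    f"= {fraction:.1%} of the ATP made per 38-min doubling"
)
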