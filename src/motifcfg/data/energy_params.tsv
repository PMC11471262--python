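# Simplified nearest-neighbor free-energy parameters (kcal/mol).
# One term per line: term <TAB> context <TAB> value.
#
# Terms:
#   stack        context "XY:ZW" = outer pair XY stacked on inner pair ZW
#                (16 Watson-Crick x Watson-Crick terms; any stack
#                involving a GU/UG pair uses stack_gu_default)
#   stack_gu_default   single value for GU-containing stacks
#   hairpin_base, hairpin_log   hairpin(n) = base + log * ln(n / 3)
#   bulge_base, internal_base, interior_slope
#                bulge(n)    = bulge_base + interior_slope * n
#                internal(n) = internal_base + interior_slope * n
#                (n = total unpaired in the loop; one shared slope)
#   ml_close, ml_branch, ml_unpaired   affine multiloop model
#   kT           Boltzmann constant x temperature (T = 310.15 K)
#
# Values are a simplified, swappable parameter set with
# nearest-neighbor-like magnitudes; the coupling mechanism, not energy
# accuracy, is what this package contributes.
stack	AU:AU	-0.9
stack	AU:UA	-1.1
stack	AU:CG	-2.2
stack	AU:GC	-2.1
stack	UA:AU	-1.3
stack	UA:UA	-0.9
stack	UA:CG	-2.4
stack	UA:GC	-2.1
stack	CG:AU	-2.1
stack	CG:UA	-2.1
stack	CG:CG	-3.3
stack	CG:GC	-2.4
stack	GC:AU	-2.4
stack	GC:UA	-2.2
stack	GC:CG	-3.4
stack	GC:GC	-3.3
stack_gu_default	-	-1.0
hairpin_base	-	5.4
hairpin_log	-	1.08
bulge_base	-	3.6
internal_base	-	3.9
interior_slope	-	0.15
ml_close	-	3.4
ml_branch	-	0.4
ml_unpaired	-	0.1
kT	-	0.6163
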