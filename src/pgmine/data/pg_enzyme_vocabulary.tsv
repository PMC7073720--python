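code	full_name	role	synonyms
COX2	Prostaglandin G/H synthase 2	synthesis	Prostaglandin G/H synthase 2|PTG/HS2|COX2|Cyclooxygenase-2|Cyclooxygenase 2|Prostaglandin-endoperoxide synthase 2|PGH synthase 2|PGHS-2
HPGDS	Hematopoietic prostaglandin D synthase	synthesis	Hematopoietic prostaglandin D synthase|HPGDS|Glutathione-requiring prostaglandin D synthase|Prostaglandin-H2 D-isomerase
PTGES2	Prostaglandin E synthase 2	synthesis	Prostaglandin E synthase 2|PTGES2|Microsomal prostaglandin E synthase 2|mPGES-2
PGE2-9-OR	Prostaglandin-E(2) 9-reductase	synthesis	Prostaglandin-E(2) 9-reductase|PGE2-9-OR|PGE(2)-9-OR|Prostaglandin E2 9-reductase|9OXORED|PGE 9-ketoreductase
PTGFS1	Prostaglandin F synthase 1	synthesis	Prostaglandin F synthase 1|PTGFS1|Prostaglandin F2-alpha synthase 1
PTGFS2	Prostaglandin F synthase 2	synthesis	Prostaglandin F synthase 2|PTGFS2|Prostaglandin F2-alpha synthase 2
15-PGDH	15-hydroxyprostaglandin dehydrogenase [NAD(+)]	catabolism	15-hydroxyprostaglandin dehydrogenase [NAD(+)]|15-hydroxyprostaglandin dehydrogenase [NAD+]|15-PGDH|15-HPGD|Prostaglandin dehydrogenase 1
PTGR1	Prostaglandin reductase 1	catabolism	Prostaglandin reductase 1|PTGR1|15-oxoprostaglandin 13-reductase|NADP-dependent leukotriene B4 12-hydroxydehydrogenase
PTGR2	Prostaglandin reductase 2	catabolism	Prostaglandin reductase 2|PTGR2
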