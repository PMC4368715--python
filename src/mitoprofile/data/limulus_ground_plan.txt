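# Arthropod mitochondrial ground-plan gene order, as exemplified by the
# horseshoe crab Limulus polyphemus (GenBank NC_003057).
# One-line signed order; a '-' prefix marks a minus-strand gene.
# Replace this file (or pass --reference) to compare against another order.
cox1 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4l trnT -trnP nad6 cob trnS2 -nad1 -trnL1 -trnL2 -rrnL -trnV -rrnS trnI -trnQ trnM nad2 trnW -trnC -trnY
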