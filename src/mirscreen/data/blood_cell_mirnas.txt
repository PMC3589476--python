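# Default blood-compartment miRNA exclusion list (editable).
#
# Placeholder list of miRNAs widely reported as predominantly derived from
# the cellular blood compartment (erythrocytes, leukocytes, platelets) and
# therefore confounded in plasma by blood counts and hemolysis. This is NOT
# the full 140-entry published list the screening design cites (that list is
# external); it is a short default that users should replace with their own.
# One canonical name per line; lines starting with '#' are ignored.
mir-16
mir-16-2*
mir-15a
mir-15b
mir-451
mir-486-5p
mir-92a
mir-92a-1*
mir-25
mir-144
mir-144*
mir-142-3p
mir-142-5p
mir-222
mir-223
mir-223*
mir-106a
mir-106b
mir-19b
mir-20a
mir-20b
mir-21
mir-26a
mir-126
mir-126*
mir-150
mir-151-5p
mir-181a
mir-185
mir-191
mir-484
let-7g
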