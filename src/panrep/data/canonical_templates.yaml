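# Strict Chothia-SDR canonical structure templates (curated data, configurable).
#
# Each record defines one canonical class of one hypervariable loop:
#   window : [start, end] Kabat position numbers of the Chothia-style loop
#            window over which the loop length is measured (insertion-lettered
#            codes count toward their base number's window)
#   length : number of residues the class requires inside that window
#   keys   : structurally determining residues; "allowed" lists the amino
#            acids compatible with the class. One violated key residue
#            disqualifies the template ("strict" matching).
#
# Key-residue sets are drawn from published Chothia/SDR compilations and may
# be replaced wholesale by pointing the loader at another file. A loop whose
# observed window length matches no template is labelled "X"; a loop whose
# length matches but whose key residues violate every length-compatible
# template is labelled "unmatched".
templates:
  - {chain: heavy, loop: H1, class: "1", window: [26, 35], length: 10,
     keys: [{code: "26", allowed: "G"}, {code: "27", allowed: "FYGT"},
            {code: "29", allowed: "FILVS"}, {code: "34", allowed: "MILVTW"}]}
  - {chain: heavy, loop: H1, class: "2", window: [26, 35], length: 11,
     keys: [{code: "26", allowed: "G"}, {code: "27", allowed: "FYGT"},
            {code: "29", allowed: "FILVS"}]}
  - {chain: heavy, loop: H1, class: "3", window: [26, 35], length: 12,
     keys: [{code: "26", allowed: "G"}, {code: "27", allowed: "FYGT"}]}
  - {chain: heavy, loop: H2, class: "1", window: [50, 58], length: 9,
     keys: [{code: "71", allowed: "RKVAL"}]}
  - {chain: heavy, loop: H2, class: "4", window: [50, 58], length: 11,
     keys: [{code: "71", allowed: "RK"}, {code: "54", allowed: "GSND"}]}
  - {chain: lambda, loop: L1, class: "2", window: [24, 34], length: 11,
     keys: [{code: "25", allowed: "GSAT"}, {code: "34", allowed: "YFNH"}]}
  - {chain: lambda, loop: L1, class: "5", window: [24, 34], length: 13,
     keys: [{code: "25", allowed: "GSAT"}, {code: "34", allowed: "YFNH"}]}
  - {chain: lambda, loop: L1, class: "6", window: [24, 34], length: 14,
     keys: [{code: "25", allowed: "GSAT"}, {code: "34", allowed: "YFNH"}]}
  - {chain: lambda, loop: L2, class: "1", window: [50, 56], length: 7,
     keys: [{code: "48", allowed: "IVLM"}]}
  - {chain: lambda, loop: L3, class: "4", window: [89, 97], length: 9,
     keys: [{code: "90", allowed: "SAQNT"}, {code: "97", allowed: "GSAV"}]}
  - {chain: lambda, loop: L3, class: "5", window: [89, 97], length: 11,
     keys: [{code: "90", allowed: "SAQNT"}, {code: "97", allowed: "GSAV"}]}
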