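;; Default conserved-sequence-block consensus library (synthetic composites
;; built around canonical vertebrate CSB cores; edit freely -- CSB calls on
;; real data depend on the motif library supplied).
>CSB-D
TATTACTAACGGTTCAAGGACATAATC
>CSB-I
TTAATGTAGTAAGAACCGACCAACGATTTATCAGTA
>CSB-II
ATAAACCCCCCTTCCCCCCTAGACCCCCCCGTCAAACCCCAAAAACACTAC
>CSB-III
TGTCAAACCCCCTACCCACCTACTAAGCTACTGTT
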