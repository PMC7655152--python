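hsa-let-7e-5p
hsa-mir-185-5p
hsa-mir-369-3p
hsa-mir-519b-3p
hsa-mir-214-3p
hsa-mir-155-5p
hsa-mir-222-3p
hsa-mir-195-5p
hsa-mir-145-5p
hsa-mir-29a-3p
hsa-mir-630
hsa-mir-106b-5p
hsa-mir-100-5p
hsa-mir-622
hsa-mir-210-5p
hsa-mir-21-5p
hsa-mir-124-3p
hsa-mir-221-3p
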