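{
 "patch_size": 7,
 "subsamples": 0,
 "checksum": "4b008fec0052d481b7e5c032dd8917d98c4abb52674fbbdde7f2c9b22a747659",
 "re_m11": [
  [
   "0x0.0p+0",
   "-0x1.ed06020e602f0p-7",
   "-0x1.379f8217237fcp-6",
   "0x0.0p+0",
   "0x1.379f8217237fcp-6",
   "0x1.ed06020e602eep-7",
   "0x0.0p+0"
  ],
  [
   "-0x1.6f6a02ffacd95p-6",
   "-0x1.7d8871b02d8e5p-5",
   "-0x1.7e225515a4f1bp-6",
   "0x0.0p+0",
   "0x1.7e225515a4f1bp-6",
   "0x1.7d8871b02d8e3p-5",
   "0x1.6f6a02ffacd9fp-6"
  ],
  [
   "-0x1.d5b4ddea9abe7p-5",
   "-0x1.7e225515a4f1bp-5",
   "-0x1.7e225515a4f1bp-6",
   "0x0.0p+0",
   "0x1.7e225515a4f1bp-6",
   "0x1.7e225515a4f1bp-5",
   "0x1.d5b4ddea9abe9p-5"
  ],
  [
   "-0x1.1a9eb99801fdap-4",
   "-0x1.7e225515a4f1bp-5",
   "-0x1.7e225515a4f1bp-6",
   "0x0.0p+0",
   "0x1.7e225515a4f1bp-6",
   "0x1.7e225515a4f1bp-5",
   "0x1.1a9eb99801fdbp-4"
  ],
  [
   "-0x1.d5b4ddea9abe7p-5",
   "-0x1.7e225515a4f1bp-5",
   "-0x1.7e225515a4f1bp-6",
   "0x0.0p+0",
   "0x1.7e225515a4f1bp-6",
   "0x1.7e225515a4f1bp-5",
   "0x1.d5b4ddea9abe9p-5"
  ],
  [
   "-0x1.6f6a02ffacd93p-6",
   "-0x1.7d8871b02d8e4p-5",
   "-0x1.7e225515a4f1ap-6",
   "0x0.0p+0",
   "0x1.7e225515a4f1ap-6",
   "0x1.7d8871b02d8e2p-5",
   "0x1.6f6a02ffacd9cp-6"
  ],
  [
   "0x0.0p+0",
   "-0x1.ed06020e602f8p-7",
   "-0x1.379f821723800p-6",
   "0x0.0p+0",
   "0x1.379f821723800p-6",
   "0x1.ed06020e602f7p-7",
   "0x0.0p+0"
  ]
 ],
 "im_m11": [
  [
   "0x0.0p+0",
   "-0x1.6f6a02ffacd96p-6",
   "-0x1.d5b4ddea9abeap-5",
   "-0x1.1a9eb99801fd8p-4",
   "-0x1.d5b4ddea9abeap-5",
   "-0x1.6f6a02ffacd93p-6",
   "0x0.0p+0"
  ],
  [
   "-0x1.ed06020e602efp-7",
   "-0x1.7d8871b02d8e5p-5",
   "-0x1.7e225515a4f1cp-5",
   "-0x1.7e225515a4f1cp-5",
   "-0x1.7e225515a4f1cp-5",
   "-0x1.7d8871b02d8e3p-5",
   "-0x1.ed06020e602fdp-7"
  ],
  [
   "-0x1.379f8217237ffp-6",
   "-0x1.7e225515a4f1cp-6",
   "-0x1.7e225515a4f1cp-6",
   "-0x1.7e225515a4f1cp-6",
   "-0x1.7e225515a4f1cp-6",
   "-0x1.7e225515a4f1bp-6",
   "-0x1.379f821723801p-6"
  ],
  [
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0"
  ],
  [
   "0x1.379f8217237ffp-6",
   "0x1.7e225515a4f1cp-6",
   "0x1.7e225515a4f1cp-6",
   "0x1.7e225515a4f1cp-6",
   "0x1.7e225515a4f1cp-6",
   "0x1.7e225515a4f1bp-6",
   "0x1.379f821723801p-6"
  ],
  [
   "0x1.ed06020e602ebp-7",
   "0x1.7d8871b02d8e3p-5",
   "0x1.7e225515a4f1ap-5",
   "0x1.7e225515a4f1ap-5",
   "0x1.7e225515a4f1ap-5",
   "0x1.7d8871b02d8e1p-5",
   "0x1.ed06020e602fap-7"
  ],
  [
   "0x0.0p+0",
   "0x1.6f6a02ffacd9ap-6",
   "0x1.d5b4ddea9abebp-5",
   "0x1.1a9eb99801fd9p-4",
   "0x1.d5b4ddea9abebp-5",
   "0x1.6f6a02ffacd99p-6",
   "0x0.0p+0"
  ]
 ],
 "m20": [
  [
   "0x0.0p+0",
   "0x1.701627276b80dp-6",
   "0x1.428c27a833570p-5",
   "0x1.4402641df6e6dp-5",
   "0x1.428c27a833570p-5",
   "0x1.701627276b80ap-6",
   "0x0.0p+0"
  ],
  [
   "0x1.701627276b80bp-6",
   "0x1.bc1b0a52c6c0ap-6",
   "-0x1.a287203c46f0bp-7",
   "-0x1.aba05305ef704p-6",
   "-0x1.a287203c46f0bp-7",
   "0x1.bc1b0a52c6c09p-6",
   "0x1.701627276b815p-6"
  ],
  [
   "0x1.428c27a833570p-5",
   "-0x1.a287203c46f0dp-7",
   "-0x1.b02cec6ac3b00p-5",
   "-0x1.0eada6ef54d60p-4",
   "-0x1.b02cec6ac3b00p-5",
   "-0x1.a287203c46f0cp-7",
   "0x1.428c27a83356fp-5"
  ],
  [
   "0x1.4402641df6e64p-5",
   "-0x1.aba05305ef704p-6",
   "-0x1.0eada6ef54d60p-4",
   "-0x1.4544d7a947d3dp-4",
   "-0x1.0eada6ef54d60p-4",
   "-0x1.aba05305ef702p-6",
   "0x1.4402641df6e71p-5"
  ],
  [
   "0x1.428c27a833570p-5",
   "-0x1.a287203c46f0dp-7",
   "-0x1.b02cec6ac3b00p-5",
   "-0x1.0eada6ef54d60p-4",
   "-0x1.b02cec6ac3b00p-5",
   "-0x1.a287203c46f0cp-7",
   "0x1.428c27a83356fp-5"
  ],
  [
   "0x1.701627276b809p-6",
   "0x1.bc1b0a52c6c08p-6",
   "-0x1.a287203c46f0dp-7",
   "-0x1.aba05305ef704p-6",
   "-0x1.a287203c46f0dp-7",
   "0x1.bc1b0a52c6c07p-6",
   "0x1.701627276b813p-6"
  ],
  [
   "0x0.0p+0",
   "0x1.701627276b812p-6",
   "0x1.428c27a833572p-5",
   "0x1.4402641df6e6dp-5",
   "0x1.428c27a833572p-5",
   "0x1.701627276b811p-6",
   "0x0.0p+0"
  ]
 ]
}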