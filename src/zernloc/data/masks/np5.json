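{
 "patch_size": 5,
 "subsamples": 0,
 "checksum": "c9505d3cf11818ed0dc78fabb958ff3a0fc10387a53b7734ebe1e44aba5dc933",
 "re_m11": [
  [
   "-0x1.e098ead65b7abp-7",
   "-0x1.7ff15cdc65a3cp-5",
   "0x0.0p+0",
   "0x1.7ff15cdc65a3dp-5",
   "0x1.e098ead65b79ep-7"
  ],
  [
   "-0x1.7e4b17e4b17e4p-4",
   "-0x1.0624dd2f1a9fdp-4",
   "0x0.0p+0",
   "0x1.0624dd2f1a9fep-4",
   "0x1.7e4b17e4b17e2p-4"
  ],
  [
   "-0x1.00aec33e1f671p-3",
   "-0x1.0624dd2f1a9fdp-4",
   "0x0.0p+0",
   "0x1.0624dd2f1a9fep-4",
   "0x1.00aec33e1f670p-3"
  ],
  [
   "-0x1.7e4b17e4b17e5p-4",
   "-0x1.0624dd2f1a9fep-4",
   "0x0.0p+0",
   "0x1.0624dd2f1a9fep-4",
   "0x1.7e4b17e4b17e3p-4"
  ],
  [
   "-0x1.e098ead65b79ep-7",
   "-0x1.7ff15cdc65a3cp-5",
   "0x0.0p+0",
   "0x1.7ff15cdc65a3bp-5",
   "0x1.e098ead65b79bp-7"
  ]
 ],
 "im_m11": [
  [
   "-0x1.e098ead65b7a9p-7",
   "-0x1.7e4b17e4b17e4p-4",
   "-0x1.00aec33e1f672p-3",
   "-0x1.7e4b17e4b17e5p-4",
   "-0x1.e098ead65b79dp-7"
  ],
  [
   "-0x1.7ff15cdc65a3cp-5",
   "-0x1.0624dd2f1a9fdp-4",
   "-0x1.0624dd2f1a9fdp-4",
   "-0x1.0624dd2f1a9fep-4",
   "-0x1.7ff15cdc65a38p-5"
  ],
  [
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0",
   "0x0.0p+0"
  ],
  [
   "0x1.7ff15cdc65a3cp-5",
   "0x1.0624dd2f1a9fdp-4",
   "0x1.0624dd2f1a9fdp-4",
   "0x1.0624dd2f1a9fep-4",
   "0x1.7ff15cdc65a39p-5"
  ],
  [
   "0x1.e098ead65b7a0p-7",
   "0x1.7e4b17e4b17e2p-4",
   "0x1.00aec33e1f671p-3",
   "0x1.7e4b17e4b17e3p-4",
   "0x1.e098ead65b79bp-7"
  ]
 ],
 "m20": [
  [
   "0x1.205bc01a36e32p-6",
   "0x1.e77b17c2acf90p-5",
   "0x1.9e66cb277ff68p-5",
   "0x1.e77b17c2acf90p-5",
   "0x1.205bc01a36e2cp-6"
  ],
  [
   "0x1.e77b17c2acf8ep-5",
   "-0x1.91f4421506b05p-5",
   "-0x1.9ab138636571cp-4",
   "-0x1.91f4421506b08p-5",
   "0x1.e77b17c2acf8cp-5"
  ],
  [
   "0x1.9e66cb277ff66p-5",
   "-0x1.9ab138636571cp-4",
   "-0x1.363427de23c59p-3",
   "-0x1.9ab138636571dp-4",
   "0x1.9e66cb277ff6cp-5"
  ],
  [
   "0x1.e77b17c2acf90p-5",
   "-0x1.91f4421506b07p-5",
   "-0x1.9ab138636571cp-4",
   "-0x1.91f4421506b09p-5",
   "0x1.e77b17c2acf8ep-5"
  ],
  [
   "0x1.205bc01a36e2cp-6",
   "0x1.e77b17c2acf90p-5",
   "0x1.9e66cb277ff6ap-5",
   "0x1.e77b17c2acf92p-5",
   "0x1.205bc01a36e2ap-6"
  ]
 ]
}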