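{
 "element_photon_xs.tsv": {
  "sha256": "ca86a9cb340bee30b1dcfba20c6c45ed72dfdb9de234c9eea87e88453eb8f304",
  "provenance": "embedded transcription + closed-form Klein-Nishina; frozen at package build"
 }
}
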