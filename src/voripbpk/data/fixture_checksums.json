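{
 "drug_parameters": "74e3d45d9958f661e9c56fdc9cd879654f51dca8c0d9cceb13d71bb96697f32a",
 "adult_validation": "da51feec3a69039473843fb22787d2099ae7a1c839688f43933d953c7f1b454e",
 "pediatric_validation": "79576d657958acf41e02d3acaae26e187a558a1e13be5bfff20a4eff403f15c7",
 "dose_recommendations": "eba74858205d4ae13db023b397518a5280e767329ac36676ca2f44937d7d3129",
 "mic_fixtures": "d2199c6b1b3fa60c646ceb5df40462aa09ccc3b73cd5387a13185f1b95a0ddc8"
}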