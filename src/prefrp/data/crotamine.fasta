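>crotamine_1H5O chain A, mature crotamine, Crotalus durissus terrificus
YKQCHKKGGHCFPKEKICLPPSSDFGKMDCRWRWKCCKKGSG
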