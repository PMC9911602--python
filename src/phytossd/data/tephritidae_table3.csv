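species,family,dose_gy,n_treated,highest_fail_dose_gy,source
Anastrepha fraterculus,Tephritidae,41.48,,,combined literature estimate
Anastrepha ludens,Tephritidae,66.58,,,combined literature estimate
Anastrepha obliqua,Tephritidae,59.78,,,combined literature estimate
Anastrepha serpentina,Tephritidae,60,,,combined literature estimate
Anastrepha striata,Tephritidae,40,,,combined literature estimate
Anastrepha suspensa,Tephritidae,51.13,,,combined literature estimate
Bactrocera cucurbitae,Tephritidae,144,,,combined literature estimate
Bactrocera dorsalis,Tephritidae,116,,,combined literature estimate
Bactrocera near dorsalis,Tephritidae,100,,,combined literature estimate
Bactrocera jarvisi,Tephritidae,101,,,combined literature estimate
Bactrocera tryoni,Tephritidae,86.26,,,combined literature estimate
Bactrocera zonata,Tephritidae,55,,,combined literature estimate
Ceratitis capitata,Tephritidae,114.21,,,combined literature estimate
Rhagoletis indifferens,Tephritidae,18,,,combined literature estimate
Rhagoletis pomonella,Tephritidae,20,,,combined literature estimate
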