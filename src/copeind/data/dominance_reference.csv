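taxon,MA,RA,OR
Calanoid copepodites,217.24,28.06,100.0
Paracalanus aculeatus,142.79,18.44,88.0
Clausocalanus furcatus,37.14,4.80,96.0
Canthocalanus pauper,27.79,3.59,96.0
Oncaea venusta,19.30,2.49,100.0
Acrocalanus gracilis,20.10,2.60,92.0
Paracalanus parvus,25.02,3.23,68.0
Temora turbinata,25.89,3.34,64.0
Farranula gibbula,18.08,2.34,88.0
Oncaea media,18.36,2.37,72.0
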