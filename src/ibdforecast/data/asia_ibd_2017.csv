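region,incidence,prev,prev_lo,prev_hi,ibd_death,ibd_death_lo,ibd_death_hi,bg_death,bg_death_lo,bg_death_hi,initial_cases,start_year
Iran,3.11,27.0,24.6,29.6,0.16,0.06,0.19,463.97,452.58,477.04,23812,2017
High-income Asia-Pacific,2.784,36.4,33.7,39.3,0.37,0.3,0.49,931.03,921.89,940.28,89447,2017
East Asia,1.541,134.6,123.9,145.6,0.34,0.28,0.39,752.33,661.03,848.26,2767000,2017
Southeast Asia,0.804,15.3,13.9,16.8,0.22,0.17,0.26,651.29,604.0,721.04,103884,2017
North Africa and Middle East,3.121,29.6,26.2,33.8,0.17,0.14,0.2,509.71,462.58,561.06,166817,2017
South Asia (India),8.133,16.2,14.7,17.9,0.3,0.21,0.4,675.31,606.15,749.66,212451,2017
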