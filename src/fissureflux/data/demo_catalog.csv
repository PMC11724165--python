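event_id,year,magnitude,rupture_length_km
demo-2021-A,2021,7.4,
demo-2022-B,2022,6.9,
demo-2001-C,2001,8.1,
demo-1951-D,1951,7.0,42.0
demo-0200bc-E,-199,7.2,
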