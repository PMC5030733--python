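row,1,2,3,4,5,6,7,8,9,10,11,12
Row 1,44.9,45.1,46.9,49.7,44.1,44.9,47.9,42.8,46.3,50.2,54.5,50.5
Row 2,53.1,53.0,53.3,46.6,46.7,54.8,51.6,49.0,47.4,48.6,46.7,45.5
Row 3,48.0,51.6,51.1,48.6,53.4,53.7,57.2,44.8,40.5,51.5,53.4,50.0
Row 4,50.6,51.2,49.3,44.7,50.0,52.0,51.1,54.6,54.3,57.7,54.9,41.5
Row 5,45.1,56.9,54.6,56.6,56.4,54.2,48.2,46.1,50.7,55.1,52.3,52.8
Row 6,53.7,55.0,58.9,43.6,48.7,59.5,54.8,50.6,52.8,55.7,56.4,46.8
Row 7,46.8,53.1,52.1,53.3,55.0,54.0,56.4,43.9,43.1,49.4,53.6,50.6
Row 8,47.5,49.3,48.3,45.4,47.0,50.1,49.6,45.9,48.4,48.1,52.6,49.7
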