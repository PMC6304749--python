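scenario,maturation,stp_class,IF_hz,msf_before,msf_after,printed_pct,printed_direction,recomputed_pct,recomputed_direction,consistent
B-2,immature,STF2,5.0,25.8,6.0,76.7,reduction,76.7,reduction,True
B-2,immature,STD1,5.0,25.8,18.0,30.2,reduction,30.2,reduction,True
B-2,immature,STF1,10.0,53.0,17.0,67.9,reduction,67.9,reduction,True
B-2,immature,STF1,15.0,47.0,18.0,61.7,reduction,61.7,reduction,True
B-2,immature,STF2,15.0,47.0,24.0,48.9,reduction,48.9,reduction,True
B-2,immature,STF1,20.0,54.0,35.8,22.5,reduction,33.7,reduction,False
B-2,immature,STF1,30.0,85.0,49.0,42.3,reduction,42.4,reduction,False
B-2,immature,STF2,30.0,85.0,43.8,48.5,reduction,48.5,reduction,True
B-3,immature,STD1,80.0,133.8,15.2,88.6,reduction,88.6,reduction,True
B-3,immature,STD2,80.0,133.8,72.8,45.6,reduction,45.6,reduction,True
B-3,immature,STD1,55.0,108.2,64.9,40.0,reduction,40.0,reduction,True
B-3,immature,STD2,55.0,108.2,66.5,38.5,reduction,38.5,reduction,True
B-4,immature,STD1,40.0,110.0,60.5,45.0,reduction,45.0,reduction,True
B-4,immature,STF2,20.0,107.7,127.0,17.9,increase,17.9,increase,True
B-4,immature,STF1,45.0,110.5,76.0,31.2,reduction,31.2,reduction,True
B-4,immature,STF2,45.0,110.5,67.2,39.2,reduction,39.2,reduction,True
B-4,immature,STF1,55.0,109.1,81.0,25.7,reduction,25.8,reduction,False
B-4,immature,STF2,55.0,109.1,94.5,13.4,reduction,13.4,reduction,True
B-4,immature,STD2,80.0,136.5,133.5,2.2,reduction,2.2,reduction,True
B-1,immature,STD1,20.0,65.0,36.0,44.6,reduction,44.6,reduction,True
B-1,immature,STF1,20.0,65.0,38.0,41.5,reduction,41.5,reduction,True
B-1,immature,STF2,20.0,65.0,78.2,20.3,increase,20.3,increase,True
B-1,immature,STD2,25.0,62.5,39.8,36.3,reduction,36.3,reduction,True
B-1,immature,STF2,45.0,90.5,65.5,27.6,reduction,27.6,reduction,True
B-1,immature,STD1,80.0,139.0,72.8,47.6,reduction,47.6,reduction,True
B-2,immature,STF2,40.0,112.0,66.8,40.3,reduction,40.4,reduction,False
B-2,immature,STF1,50.0,86.0,82.0,4.6,reduction,4.7,reduction,False
B-2,immature,STF2,50.0,86.0,76.0,11.6,reduction,11.6,reduction,True
B-2,immature,STD2,100.0,152.7,89.5,41.4,reduction,41.4,reduction,True
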