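# Published per-strategy incremental cost and effects vs no screening, per 1,000 persons,
# under four assumption columns: default (average mortality, no background costs/disutility),
# and background costs/disutility/mortality at 100%/125%/150% of population averages.
# Units: colorectal (crc) cost cells are $ millions per 1000 adults; esophageal (eac) cost
# cells are $ thousands per 1000 men (the thousands reading is the one that reproduces the
# printed ICERs). ICER cells: dollars per QALY gained vs the next less effective efficient
# strategy; "Ref." = frontier reference, "Dom." = dominated (strongly or extendedly).
disease,strategy,cost_default,ly_default,qaly_default,icer_default,cost_100,ly_100,qaly_100,icer_100,cost_125,ly_125,qaly_125,icer_125,cost_150,ly_150,qaly_150,icer_150
crc,No screening,0.0,0.0,0.0,Dom.,0.0,0.0,0.0,Dom.,0.0,0.0,0.0,Dom.,0.0,0.0,0.0,Ref.
crc,"Colonoscopy, 55-75, 15",-1.81,64.7,70.5,Ref.,-0.98,64.7,55.1,Ref.,-0.06,54.7,42.9,Ref.,0.55,47.0,33.7,16400
crc,"Colonoscopy, 55-85, 15",-1.75,65.0,70.4,Dom.,-0.91,65.0,55.0,Dom.,-0.00,54.9,42.7,Dom.,0.59,47.2,33.5,Dom.
crc,"Colonoscopy, 55-75, 10",-1.80,68.1,73.5,3300,-0.92,68.1,57.3,25100,0.07,57.5,44.4,Dom.,0.72,49.5,34.8,Dom.
crc,"Colonoscopy, 55-85, 10",-1.75,68.3,73.3,Dom.,-0.87,68.3,57.1,Dom.,0.12,57.7,44.2,Dom.,0.76,49.6,34.6,Dom.
crc,"Colonoscopy, 55-75, 5",-1.51,71.8,75.3,Dom.,-0.59,71.8,58.2,Dom.,0.49,60.8,44.7,Dom.,1.19,52.3,34.6,Dom.
crc,"Colonoscopy, 55-80, 5",-1.46,72.2,75.2,Dom.,-0.53,72.2,58.0,Dom.,0.55,61.0,44.5,Dom.,1.25,52.5,34.4,Dom.
crc,"Colonoscopy, 55-85, 5",-1.41,72.2,74.9,Dom.,-0.47,72.2,57.7,Dom.,0.59,61.0,44.2,Dom.,1.29,52.5,34.2,Dom.
crc,"Colonoscopy, 50-75, 15",-1.67,71.4,77.4,Dom.,-0.77,71.4,60.6,Dom.,0.22,61.1,47.8,57400,0.90,53.2,38.0,80800
crc,"Colonoscopy, 50-80, 15",-1.64,72.7,78.1,Dom.,-0.72,72.7,61.1,Dom.,0.28,62.0,47.9,Dom.,0.95,53.9,37.9,Dom.
crc,"Colonoscopy, 50-75, 10",-1.66,77.3,82.9,15600,-0.68,77.3,64.7,32600,0.41,66.2,50.8,61100,1.15,57.6,40.3,111100
crc,"Colonoscopy, 50-80, 10",-1.62,78.1,83.1,Dom.,-0.63,78.1,64.8,Dom.,0.47,66.7,50.7,Dom.,1.21,58.0,40.1,Dom.
crc,"Colonoscopy, 50-75, 5",-1.15,82.6,84.9,Dom.,-0.11,82.6,65.6,Dom.,1.09,70.7,50.8,Dom.,1.91,61.6,39.7,Dom.
crc,"Colonoscopy, 50-80, 5",-1.09,82.9,84.8,Dom.,-0.48,82.9,65.3,Dom.,1.16,71.0,50.6,Dom.,1.97,61.8,39.4,Dom.
crc,"Colonoscopy, 50-85, 5",-1.04,83.0,84.5,Dom.,0.00,83.0,65.1,Dom.,1.20,71.0,50.3,Dom.,2.00,61.8,39.2,Dom.
crc,"Colonoscopy, 45-75, 15",-1.40,77.4,82.1,Dom.,-0.44,77.4,64.1,Dom.,0.62,66.5,50.5,Dom.,1.34,58.2,40.1,Dom.
crc,"Colonoscopy, 45-75, 10",-1.31,83.6,87.8,71700,-0.27,83.6,68.4,114600,0.91,72.0,53.8,169200,1.71,63.1,42.6,236800
crc,"Colonoscopy, 45-85, 10",-1.25,83.8,87.6,Dom.,-0.21,83.8,68.2,Dom.,0.95,72.1,53.5,Dom.,1.74,63.2,42.4,Dom.
crc,"Colonoscopy, 45-75, 5",-0.56,90.1,89.9,354000,0.56,90.1,69.0,1222700,1.85,77.8,53.6,Dom.,2.74,68.3,41.7,Dom.
crc,"Colonoscopy, 45-80, 5",-0.50,90.4,89.7,Dom.,0.62,90.4,68.8,Dom.,1.92,78.0,53.3,Dom.,2.81,68.5,41.5,Dom.
crc,"Colonoscopy, 45-85, 5",-0.45,90.4,89.5,Dom.,0.67,90.4,68.5,Dom.,1.96,78.1,53.0,Dom.,2.84,68.5,41.3,Dom.
eac,No screening,0.0,0.0,0.0,Ref.,0.0,0.0,0.0,Ref.,0.0,0.0,0.0,Ref.,0.0,0.0,0.0,Ref.
eac,"Cytosponge, 60",976.2,32.8,32.4,30200,1252.9,32.8,26.4,47500,1312.2,32.1,24.3,53900,1368.4,31.4,22.4,61200
eac,"Endoscopy, 60",1618.3,40.5,38.4,106300,1959.6,40.5,31.0,152300,2032.6,39.6,28.5,173200,2101.8,38.7,26.1,198300
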