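character,kind,reference,robusta_min,robusta_max,nigra_min,nigra_max,intermedia_min,intermedia_max,grahamii_min,grahamii_max
body depth,morphometric,SL,5.2,5.4,4.1,4.6,3.7,4.0,4.5,4.5
head length,morphometric,SL,3.5,3.6,3.5,3.6,3.1,3.4,3.6,3.6
head width,morphometric,HL,1.3,1.4,1.4,1.8,1.4,1.6,1.7,1.7
head depth,morphometric,HL,1.1,1.1,1.2,1.4,1.3,1.4,1.5,1.5
snout length,morphometric,HL,3.0,3.2,3.0,3.7,3.0,4.0,3.5,3.5
mandible length,morphometric,HL,2.1,2.2,2.4,2.9,2.3,2.7,2.5,2.5
orbit diameter,morphometric,HL,5.5,8.1,4.0,6.3,3.6,5.3,2.9,2.9
interorbital width,morphometric,HL,3.1,3.2,3.0,3.9,3.2,3.3,3.1,3.1
upper-jaw length,morphometric,HL,2.5,2.9,3.1,3.5,2.4,4.0,,
caudal-peduncle depth,morphometric,BD,2.3,2.6,2.2,2.7,2.3,2.7,2.9,2.9
caudal peduncle length,morphometric,SL,2.9,4.0,4.5,5.2,4.9,6.1,4.6,4.6
predorsal length,morphometric,SL,1.8,1.9,1.7,1.8,1.7,1.8,2.0,2.0
preanal length,morphometric,SL,1.5,1.6,1.4,1.5,1.4,1.5,1.4,1.4
pectoral insertion to pelvic insertion,morphometric,SL,4.0,4.5,3.4,4.6,1.8,2.1,3.8,3.8
anal to caudal length,morphometric,SL,3.0,3.1,2.9,3.7,3.3,3.9,3.4,3.4
origin of anal fin to hypural plate,morphometric,SL,2.7,3.0,3.1,3.3,3.0,3.2,3.2,3.2
prepelvic length,morphometric,SL,1.9,2.2,1.8,2.0,1.5,1.9,1.9,1.9
pectoral-fin length,morphometric,SL,3.9,5.7,4.8,6.4,4.5,6.8,5.3,5.3
anal fin height,morphometric,SL,4.9,7.4,6.1,7.0,4.9,4.9,5.8,5.8
pelvic-fin height,morphometric,SL,5.5,5.5,5.8,7.9,5.7,6.9,6.6,6.6
dorsal fin height,morphometric,SL,4.4,6.0,4.5,6.1,4.1,5.8,5.0,5.0
caudal peduncle length/depth,ratio,,1.1,1.7,1.9,2.4,1.9,2.4,1.6,1.6
head length/caudal peduncle depth,ratio,,1.3,1.5,2.1,2.8,1.2,1.5,1.2,1.2
dorsal rays,meristic,,9,9,8,8,8,8,9,9
anal rays,meristic,,9,9,8,8,8,8,9,9
pectoral rays,meristic,,13,15,14,15,13,14,14,14
pelvic rays,meristic,,9,9,8,9,9,9,9,9
principal caudal rays,meristic,,19,23,19,22,23,25,23,23
upper procurrent caudal rays,meristic,,8,8,7,9,7,7,6,6
lateral line scales,meristic,,89,92,73,93,59,71,92,92
scales above lateral line,meristic,,21,23,18,23,16,18,25,25
scales below lateral line,meristic,,14,14,12,16,11,13,17,17
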