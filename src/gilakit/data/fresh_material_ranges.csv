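character,kind,reference,robusta_min,robusta_max,nigra_min,nigra_max,intermedia_min,intermedia_max
body depth,morphometric,SL,3.9,5.3,3.7,5.0,3.9,4.8
head length,morphometric,SL,3.4,3.9,3.3,3.8,3.5,3.8
head width,morphometric,HL,1.5,2.1,1.6,2.0,1.4,2.1
head depth,morphometric,HL,1.1,1.6,1.3,1.6,1.2,1.6
snout length,morphometric,HL,3.2,3.8,3.1,3.6,3.0,4.0
mandible length,morphometric,HL,2.5,2.8,2.3,2.8,2.4,2.6
orbit diameter,morphometric,HL,3.1,4.9,4.4,6.1,3.8,6.0
interorbital width,morphometric,HL,3.3,3.9,3.1,3.6,3.0,3.8
upper-jaw length,morphometric,HL,3.0,3.3,1.5,3.4,2.5,3.2
caudal-peduncle depth,morphometric,BD,2.1,3.1,2.3,2.8,2.3,3.2
caudal peduncle length,morphometric,SL,5.0,5.7,4.1,4.9,4.5,6.1
predorsal length,morphometric,SL,1.8,2.0,1.8,2.0,1.8,2.0
preanal length,morphometric,SL,1.4,1.6,1.4,1.5,1.4,1.6
pectoral insertion to pelvic insertion,morphometric,SL,3.6,4.0,3.5,4.0,3.3,4.0
anal to caudal length,morphometric,SL,2.9,4.2,3.0,3.5,3.1,3.8
origin of anal fin to hypural plate,morphometric,SL,2.9,3.6,2.9,4.8,3.0,4.0
prepelvic length,morphometric,SL,1.8,2.1,1.9,3.5,1.9,2.0
caudal-fin length,morphometric,SL,3.5,4.2,3.9,5.2,3.9,4.6
caudal concavity,morphometric,SL,1.8,3.0,2.6,3.5,2.1,3.0
pectoral-fin length,morphometric,SL,5.3,7.2,5.2,6.4,5.5,8.5
anal fin length,morphometric,SL,5.5,6.7,5.7,6.6,5.6,7.8
pelvic-fin length,morphometric,SL,6.7,7.8,6.3,7.7,6.5,8.8
dorsal fin length,morphometric,SL,4.4,5.4,4.5,5.5,4.6,6.6
caudal fin length,morphometric,SL,4.0,4.7,4.4,6.1,4.3,5.2
caudal peduncle length/depth,ratio,,1.6,2.5,1.5,2.1,1.5,2.6
head length/caudal peduncle depth,ratio,,1.2,1.7,1.2,1.7,1.2,1.5
dorsal rays,meristic,,8,9,8,9,8,9
anal rays,meristic,,8,9,8,9,8,9
pectoral rays,meristic,,14,16,14,16,13,15
pelvic rays,meristic,,9,9,9,9,9,9
principal caudal rays,meristic,,19,19,19,19,19,19
upper procurrent caudal rays,meristic,,8,10,6,11,7,10
lateral line scales,meristic,,82,95,82,89,65,87
scales above lateral line,meristic,,23,26,20,23,17,21
scales below lateral line,meristic,,11,15,11,15,10,14
gill rakers,meristic,,7,8,6,7,7,9
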