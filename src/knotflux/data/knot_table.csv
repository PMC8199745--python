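label,det1,det2,alexander,homfly
0.1,1,1,1,0:0:1
3.1-,3,7,1 -1 1,2:0:2;2:2:1;4:0:-1
3.1+,3,7,1 -1 1,-4:0:-1;-2:0:2;-2:2:1
4.1,5,11,-1 3 -1,-2:0:1;0:0:-1;0:2:-1;2:0:1
5.1-,5,31,1 -1 1 -1 1,4:0:3;4:2:4;4:4:1;6:0:-2;6:2:-1
5.1+,5,31,1 -1 1 -1 1,-6:0:-2;-6:2:-1;-4:0:3;-4:2:4;-4:4:1
5.2-,7,16,2 -3 2,2:0:1;2:2:1;4:0:1;4:2:1;6:0:-1
5.2+,7,16,2 -3 2,-6:0:-1;-4:0:1;-4:2:1;-2:0:1;-2:2:1
6.1-,9,20,-2 5 -2,-2:0:1;0:2:-1;2:0:-1;2:2:-1;4:0:1
6.1+,9,20,-2 5 -2,-4:0:1;-2:0:-1;-2:2:-1;0:2:-1;2:0:1
6.2-,11,59,-1 3 -3 3 -1,0:0:2;0:2:1;2:0:-2;2:2:-3;2:4:-1;4:0:1;4:2:1
6.2+,11,59,-1 3 -3 3 -1,-4:0:1;-4:2:1;-2:0:-2;-2:2:-3;-2:4:-1;0:0:2;0:2:1
6.3,13,67,1 -3 5 -3 1,-2:0:-1;-2:2:-1;0:0:3;0:2:3;0:4:1;2:0:-1;2:2:-1
7.1-,7,127,1 -1 1 -1 1 -1 1,6:0:4;6:2:10;6:4:6;6:6:1;8:0:-3;8:2:-4;8:4:-1
7.1+,7,127,1 -1 1 -1 1 -1 1,-8:0:-3;-8:2:-4;-8:4:-1;-6:0:4;-6:2:10;-6:4:6;-6:6:1
7.2-,11,25,3 -5 3,2:0:1;2:2:1;4:2:1;6:0:1;6:2:1;8:0:-1
7.2+,11,25,3 -5 3,-8:0:-1;-6:0:1;-6:2:1;-4:2:1;-2:0:1;-2:2:1
7.3+,13,76,2 -3 3 -3 2,-8:0:-2;-8:2:-1;-6:0:2;-6:2:3;-6:4:1;-4:0:1;-4:2:3;-4:4:1
7.3-,13,76,2 -3 3 -3 2,4:0:1;4:2:3;4:4:1;6:0:2;6:2:3;6:4:1;8:0:-2;8:2:-1
7.4+,15,34,4 -7 4,-8:0:-1;-6:2:1;-4:0:2;-4:2:2;-2:2:1
7.4-,15,34,4 -7 4,2:2:1;4:0:2;4:2:2;6:2:1;8:0:-1
7.5-,17,94,2 -4 5 -4 2,4:0:2;4:2:3;4:4:1;6:2:2;6:4:1;8:0:-1;8:2:-1
7.5+,17,94,2 -4 5 -4 2,-8:0:-1;-8:2:-1;-6:2:2;-6:4:1;-4:0:2;-4:2:3;-4:4:1
7.6-,19,95,-1 5 -7 5 -1,0:0:1;0:2:1;2:0:-1;2:2:-2;2:4:-1;4:0:2;4:2:2;6:0:-1
7.6+,19,95,-1 5 -7 5 -1,-6:0:-1;-4:0:2;-4:2:2;-2:0:-1;-2:2:-2;-2:4:-1;0:0:1;0:2:1
7.7+,21,103,1 -5 9 -5 1,-4:0:1;-2:0:-2;-2:2:-2;0:0:2;0:2:2;0:4:1;2:2:-1
7.7-,21,103,1 -5 9 -5 1,-2:2:-1;0:0:2;0:2:2;0:4:1;2:0:-2;2:2:-2;4:0:1
8.1-,13,29,-3 7 -3,-2:0:1;0:2:-1;2:2:-1;4:0:-1;4:2:-1;6:0:1
8.1+,13,29,-3 7 -3,-6:0:1;-4:0:-1;-4:2:-1;-2:2:-1;0:2:-1;2:0:1
3.1+#3.1+,9,49,1 -2 3 -2 1,-8:0:1;-6:0:-4;-6:2:-2;-4:0:4;-4:2:4;-4:4:1
3.1-#3.1-,9,49,1 -2 3 -2 1,4:0:4;4:2:4;4:4:1;6:0:-4;6:2:-2;8:0:1
3.1+#3.1-,9,49,1 -2 3 -2 1,-2:0:-2;-2:2:-1;0:0:5;0:2:4;0:4:1;2:0:-2;2:2:-1
3.1+#4.1,15,77,-1 4 -5 4 -1,-6:0:-1;-4:0:3;-4:2:2;-2:0:-3;-2:2:-3;-2:4:-1;0:0:2;0:2:1
3.1-#4.1,15,77,-1 4 -5 4 -1,0:0:2;0:2:1;2:0:-3;2:2:-3;2:4:-1;4:0:3;4:2:2;6:0:-1
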