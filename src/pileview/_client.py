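"""Client-side assets embedded into HTML reports.

The report carries its plot specification as one lz-string-compressed
JavaScript string.  ``LZ_DECOMPRESS_JS`` is the matching decompressor
(UTF-16-safe dialect).  In embed mode the full rendering runtime
(``RENDERER_JS`` — payload decoding, greedy row layout, SVG drawing,
read-name search, tooltips) is inlined, so the file opens with zero
network access; with ``--no-embed-js`` the Vega runtime is loaded from
pinned CDN URLs instead and only the decompressor plus a small embed shim
are inlined.
"""

# Pinned CDN runtime versions for --no-embed-js reports.
CDN_URLS = (
    "https://cdn.jsdelivr.net/npm/vega@5.30.0/build/vega.min.js",
    "https://cdn.jsdelivr.net/npm/vega-lite@5.21.0/build/vega-lite.min.js",
    "https://cdn.jsdelivr.net/npm/vega-embed@6.26.0/build/vega-embed.min.js",
)

LZ_DECOMPRESS_JS = r"""
function lzDecompressUTF16(compressed){
  if(compressed==null||compressed=="")return "";
  var dictionary=[0,1,2],enlargeIn=4,dictSize=4,numBits=3,entry="",result=[],w,c,
      data={val:compressed.charCodeAt(0)-32,position:16384,index:1};
  function readBits(n){
    var bits=0,power=1,maxpower=Math.pow(2,n),resb;
    while(power!=maxpower){
      resb=data.val&data.position;
      data.position>>=1;
      if(data.position==0){
        data.position=16384;
        data.val=(data.index<compressed.length?compressed.charCodeAt(data.index):32)-32;
        data.index++;
      }
      bits|=(resb>0?1:0)*power;power<<=1;
    }
    return bits;
  }
  switch(readBits(2)){
    case 0:c=String.fromCharCode(readBits(8));break;
    case 1:c=String.fromCharCode(readBits(16));break;
    case 2:return "";
  }
  dictionary[3]=c;w=c;result.push(c);
  while(true){
    if(data.index>compressed.length)return "";
    c=readBits(numBits);
    switch(c){
      case 0:dictionary[dictSize++]=String.fromCharCode(readBits(8));c=dictSize-1;enlargeIn--;break;
      case 1:dictionary[dictSize++]=String.fromCharCode(readBits(16));c=dictSize-1;enlargeIn--;break;
      case 2:return result.join('');
    }
    if(enlargeIn==0){enlargeIn=Math.pow(2,numBits);numBits++;}
    if(typeof dictionary[c]==="string"){entry=dictionary[c];}
    else if(c===dictSize){entry=w+w.charAt(0);}
    else{return null;}
    result.push(entry);
    dictionary[dictSize++]=w+entry.charAt(0);
    enlargeIn--;
    w=entry;
    if(enlargeIn==0){enlargeIn=Math.pow(2,numBits);numBits++;}
  }
}
"""

RENDERER_JS = r"""
(function(){
  var spec=JSON.parse(lzDecompressUTF16(PAYLOAD));
  var meta=spec.usermeta,region=meta.region,n=region.end-region.start+1;
  var width=spec.width||800,MARGIN=10,COVH=60,REFH=14,PITCH=12,READH=9;
  var bw=(width-2*MARGIN)/n;
  var showLetters=n<=2000&&bw>=4;
  function X(p){return MARGIN+Math.max(0,Math.min(n,p-region.start))*bw;}
  function XE(p){return MARGIN+Math.max(0,Math.min(n,p-region.start+1))*bw;}
  // decode the flat payload: records split on the sentinel, fields on spaces
  var packed=spec.datasets.reads[0].packed;
  var reads=packed?packed.split("\u00A7").map(function(rec){
    var f=rec.split(" ");
    return {name:f[0],pos:+f[1],mapq:+f[2],strand:f[3],edits:f[4]};
  }):[];
  function refSpan(edits){
    var span=0;
    if(edits)edits.split("|").forEach(function(t){
      var m=/^(\d+)(=|d|n|[ACGTN])$/.exec(t);
      if(m)span+=+m[1];
    });
    return span;
  }
  // group mates into fragments; rows come precomputed from the generator
  var frags={},order=[];
  reads.forEach(function(r){
    r.end=r.pos+refSpan(r.edits)-1;
    if(!frags[r.name]){frags[r.name]={name:r.name,reads:[],row:meta.rows[r.name]||1};order.push(r.name);}
    frags[r.name].reads.push(r);
  });
  var nRows=meta.n_rows||1;
  var yRef=MARGIN+COVH+4,yReads=yRef+(showLetters?REFH:0)+4;
  var height=yReads+nRows*PITCH+MARGIN;
  function lerp(a,b,t){return Math.round(a+t*(b-a));}
  function hex2rgb(h){return [parseInt(h.slice(1,3),16),parseInt(h.slice(3,5),16),parseInt(h.slice(5,7),16)];}
  function mapqColor(q){
    var stops=meta.mapq_stops;
    if(q>=stops[stops.length-1][0])return stops[stops.length-1][1];
    for(var i=0;i+1<stops.length;i++){
      if(q>=stops[i][0]&&q<=stops[i+1][0]){
        var t=(q-stops[i][0])/(stops[i+1][0]-stops[i][0]);
        var a=hex2rgb(stops[i][1]),b=hex2rgb(stops[i+1][1]);
        return "rgb("+lerp(a[0],b[0],t)+","+lerp(a[1],b[1],t)+","+lerp(a[2],b[2],t)+")";
      }
    }
    return stops[0][1];
  }
  var NS="http://www.w3.org/2000/svg";
  function el(tag,attrs,parent){
    var e=document.createElementNS(NS,tag);
    for(var k in attrs)e.setAttribute(k,attrs[k]);
    if(parent)parent.appendChild(e);
    return e;
  }
  var svg=el("svg",{width:width,height:height,viewBox:"0 0 "+width+" "+height});
  el("rect",{x:0,y:0,width:width,height:height,fill:"#FFFFFF"},svg);
  (spec.datasets.highlights||[]).forEach(function(h){
    var r=el("rect",{x:X(h.start),y:MARGIN,width:XE(h.end2-1)-X(h.start),
      height:height-2*MARGIN,fill:meta.palette.yellow,opacity:0.25},svg);
    if(h.label){var t=document.createElementNS(NS,"title");t.textContent=h.label;r.appendChild(t);}
  });
  var cov=spec.datasets.coverage,maxDepth=1;
  cov.forEach(function(c){if(c.depth>maxDepth)maxDepth=c.depth;});
  cov.forEach(function(c){
    if(c.depth>0){
      var h=COVH*c.depth/maxDepth;
      el("rect",{x:X(c.pos),y:MARGIN+COVH-h,width:Math.max(XE(c.pos)-X(c.pos),0.5),
        height:h,fill:meta.palette.blue},svg);
    }
  });
  if(showLetters)spec.datasets.reference.forEach(function(r){
    var t=el("text",{x:X(r.pos)+bw/2,y:yRef+REFH-4,"font-size":9,
      "font-family":"monospace","text-anchor":"middle",
      fill:meta.base_colors[r.base]||meta.palette.black},svg);
    t.textContent=r.base;
  });
  order.forEach(function(name){
    var f=frags[name],y=yReads+(f.row-1)*PITCH;
    var g=el("g",{"class":"fragment","data-name":f.name},svg);
    f.reads.sort(function(a,b){return a.pos-b.pos;});
    if(f.reads.length==2&&f.reads[1].pos>f.reads[0].end+1)
      el("line",{x1:XE(f.reads[0].end),y1:y+READH/2,x2:X(f.reads[1].pos),y2:y+READH/2,
        stroke:meta.palette.grey,"stroke-width":1},g);
    f.reads.forEach(function(r){
      if(r.end<region.start||r.pos>region.end)return;
      var body=el("rect",{x:X(r.pos),y:y,width:XE(r.end)-X(r.pos),height:READH,
        fill:meta.palette.grey,stroke:mapqColor(r.mapq),"stroke-width":1},g);
      var tip=document.createElementNS(NS,"title");
      var aux=meta.aux[r.name],auxText="";
      if(aux)for(var k in aux)auxText+=" "+k+"="+aux[k];
      tip.textContent=r.name+" pos="+r.pos+" MAPQ="+r.mapq+" "+r.strand+auxText;
      body.appendChild(tip);
      var pos=r.pos;
      (r.edits?r.edits.split("|"):[]).forEach(function(tok){
        var m=/^(\d+)(=|d|n|[ACGTN])$/.exec(tok);
        if(m){
          var len=+m[1],kind=m[2];
          if(kind!=="="){
            if(kind==="d"||kind==="n"){
              el("rect",{x:X(pos),y:y,width:XE(pos+len-1)-X(pos),height:READH,fill:"#FFFFFF"},g);
              el("line",{x1:X(pos),y1:y+READH/2,x2:XE(pos+len-1),y2:y+READH/2,
                stroke:kind==="d"?meta.palette.black:meta.palette.grey,
                "stroke-width":kind==="d"?1.5:0.75},g);
            }else{
              el("rect",{x:X(pos),y:y,width:Math.max(XE(pos+len-1)-X(pos),0.5),
                height:READH,fill:meta.base_colors[kind]},g);
            }
          }
          pos+=len;
        }else{
          var mi=/^i([ACGTN]+)$/.exec(tok);
          if(mi){
            var cx=X(pos);
            var p=el("polygon",{points:(cx-3)+","+y+" "+(cx+3)+","+y+" "+cx+","+(y+4),
              fill:meta.palette.purple},g);
            var it=document.createElementNS(NS,"title");
            it.textContent="insertion "+mi[1];
            p.appendChild(it);
          }
        }
      });
    });
  });
  var label=el("text",{x:width/2,y:height-1,"font-size":9,"font-family":"monospace",
    "text-anchor":"middle",fill:"#000000"},svg);
  label.textContent=region.chrom+":"+region.start+"-"+region.end;
  var app=document.getElementById("app");
  var box=document.createElement("input");
  box.type="text";box.placeholder="Filter reads by name (regex)";box.id="read-search";
  box.style.cssText="display:block;margin:6px 0;width:280px;";
  box.addEventListener("input",function(){
    var q=box.value,re=null;
    try{re=q?new RegExp(q):null;}catch(e){re=null;}
    svg.querySelectorAll("g.fragment").forEach(function(g){
      g.setAttribute("opacity",!re||re.test(g.getAttribute("data-name"))?"1":"0.15");
    });
  });
  app.appendChild(box);
  app.appendChild(svg);
})();
"""

NO_EMBED_SHIM_JS = r"""
(function(){
  var spec=JSON.parse(lzDecompressUTF16(PAYLOAD));
  vegaEmbed("#app",spec,{actions:true});
})();
"""

HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body{{font-family:sans-serif;margin:16px;}}
h1{{font-size:15px;margin:0 0 8px 0;}}
#app svg{{border:1px solid #ddd;}}
</style>
</head>
<body>
<h1>{title}</h1>
<div id="app"></div>
{runtime_scripts}<script>
var PAYLOAD={payload_literal};
{inline_js}
</script>
</body>
</html>
"""
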